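# synthetic reconstruction: curated pyoverdine/azotobactin clusters (gene order + published monomer sequences)
cluster_id	organism	siderophore_name	gene_order	monomers	fasta_path	skip
pvd_type1	Pseudomonas synthetic sp. 1	pyoverdine-like	pvdL,pvdI,pvdJ,pvdD	Ser,Arg,Ser,OHOrn,Lys,OHOrn,Thr,Thr		0
azb_like	Azotobacter synthetic sp.	azotobactin-like	avbA,avbB,avbC	Asp,Ser,Hse,Gly,OHAsp,Cit,OHOrn		0
abc1_mirror	Pseudomonas synthetic sp. ABC1-mirror	azotobactin-type	pvdL,pvdI,pvdJ,pvdD,pvdX	OHAsp,Ala,OHOrn,Arg,Thr,Hse,Cit,Cit,OHAsp,Ser,OHOrn		0
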