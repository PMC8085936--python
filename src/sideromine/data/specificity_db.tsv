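# synthetic reconstruction of a pyoverdine/azotobactin specificity knowledge base (codes are not literature codes)
stachelhaus_code	extended_code	monomer	source_cluster	protein_id	module_index
DFWMCCRRKK	KNHDFWQNGFQIMCCYRRKREQWIPYYDDTVATK	Ala	synthetic_kb_v1	kbA	0
DKDNVEIGAK	QSMDKDSTCDNYNVEPIGAPYDYWQWLLTCAWMK	Arg	synthetic_kb_v1	kbA	1
DLDRSGDPSK	PYVDLDDLMIDLRSGTDPSNSSCVQLSRPAIVNK	Asn	synthetic_kb_v1	kbA	2
DYLTHNRTPK	GFTDYLWMVLTGTHNPRTPCQDDGALVDMEDLHK	Asp	synthetic_kb_v1	kbA	3
DEHKTRLTTK	PIADEHQAYHWDKTRTLTTMDPDYVKNYPGWVAK	OHAsp	synthetic_kb_v1	kbA	4
DGTRTASHYK	VEEDGTNSRGKNRTAQSHYAADSESVHRADKIQK	Cit	synthetic_kb_v1	kbA	5
DCGAAPVEYK	RRKDCGNSGPDYAAPLVEYASQPDGWCYQPWIDK	Dab	synthetic_kb_v1	kbA	6
DTGNYCISKK	YHCDTGQLRGQSNYCHISKYHWTRHVDWDCYPIK	Gln	synthetic_kb_v1	kbA	7
DLAHVMGMTK	RKYDLATGIFMWHVMKGMTRTYPAWGTPARRWWK	Glu	synthetic_kb_v1	kbA	8
DWEGWQCPWK	IAHDWEWKSFIFGWQLCPWDCIEQSCYDEWLHIK	Gly	synthetic_kb_v1	kbA	9
DCFIYKWWVK	TYWDCFMRNNPHIYKVWWVANEEVDSETHFNIIK	His	synthetic_kb_v1	kbA	10
DYGYMRDAYK	NHRDYGKVCVFQYMRRDAYEWALDRARAEGYFFK	Hse	synthetic_kb_v1	kbA	11
DGSTLKFPPK	AQPDGSQHALERTLKMFPPRDMVQLYDGKIHNYK	Ile	synthetic_kb_v1	kbA	12
DPMRGYDHLK	PTWDPMAGCPMIRGYPDHLCDLPNRLNFNSYYPK	Leu	synthetic_kb_v1	kbA	13
DAREDLGVNK	HGDDARGVICYQEDLMGVNHCNWPWHIPIFVEHK	Lys	synthetic_kb_v1	kbA	14
DKVQAATRYK	AWPDKVKMQKGAQAAYTRYSKYCRQNTHNYEGDK	OHOrn	synthetic_kb_v1	kbA	15
DMQIVSHHDK	SFFDMQMAKRPHIVSSHHDRPYPHIHIRCFAYGK	Orn	synthetic_kb_v1	kbA	16
DKMDGSIFPK	EWNDKMMFWTSQDGSDIFPEAQATADDRGAQTMK	Phe	synthetic_kb_v1	kbA	17
DRRCRIWTNK	KCNDRRPGDWYTCRISWTNSEYYKHWVQHMWKEK	Ser	synthetic_kb_v1	kbA	18
DACHQQVCPK	QQCDACVTVDECHQQAVCPCAAEGHPFKFQYRVK	Thr	synthetic_kb_v1	kbA	19
DNNVQFWSVK	WCKDNNAAHGLHVQFAWSVRQHGFVIQSDIFWTK	Trp	synthetic_kb_v1	kbA	20
DGMISHQDVK	VTMDGMKEIDQHISHIQDVMDANFPNEWRWRYIK	Tyr	synthetic_kb_v1	kbA	21
DKFLTMKPLK	HLIDKFPKDYFMLTMNKPLQTTNWRKIIPGFTAK	Val	synthetic_kb_v1	kbA	22
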