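>scaffold_A synthetic NRPS domain scaffold
GRGIRTEVDPSEMNAESANRYKMRNSGTGLETKAGCTNQAQDFDESTTDSSDVCKPIVEI
GSDKENQVLEIENPSRLKACLLNRKVPGMAVKAVGDDVQSPAYLFEFEMTRDTFVGISLL
SKWGSVYGFAIKPGSLNMRAVNLEISGTDCGLLAKQRPVDDRADGELAADCGVAVEESKS
HAKLWWIAPLDDFAHRELGAGVYRLKNDNGLEDDSSFTPPTSVPKTRCTPIICTDAVPWA
ATPLLKVEHATVIAEQTTFAEVLAIKMTLICPLYAPDTLFGYEFPETLEGVIEDESGMIL
AYRYTNGEKFLRTQIKMLGAAAISYFMRLICYDEEYQDLLMVVNSSYAVLELIEPFLAHD
ITTPLIDVRKLISKRETVTVVCSPLSARGVSIFFLLFIRPTIPQYGQLRLQHYNIGEEFY
LNEAKPWRNAVVHVAKYDGHNAIMTLDEEKYKIRRFSVISRPKVAELPTGVLDGLGPWVR
PEETGDKGGFVTWLYLPTLAVSDRALEGHVVEPHKAKPEFAGAGITRKDE
>scaffold_C synthetic NRPS domain scaffold
QIDADSVMVKKSYGYQLGWRKKIAAQWSVQATGDCSIHTDNGTALYFPHKTSMHRQEIVI
EGFRGCFLVGNQGFFKPTLNLEMLYALHSRLLTPGLGGMGGNICHMGYGDSNKVYNRKRM
SAVMVSSVMLIKYKTPGAIEPYGIDVQERHGYCGIVLMQKDFMVATAERMRSISPSKTRS
QVGLDVMTIKGVSETHGRALSTPETGASEQMALLNRTDELQLNWQHKSSIWKHATTLDGN
KEDGIVHCKEYTDKFYFEYNHVEEQVMVGDVRMGLGGHKVILTVWNLERGWRDAQMSFKR
KCPGTLQLCAKPRDVESALNYLAIEVGIAKAVEKYRPIIILVDAGVRIGKEVGRYINETR
GTEDDKKRHSEMQHIVTTACLKNLRRMEELGDRRALTRSAEQSYQLLIELDKVDRITLPL
KYKAAAVESAGGSQSAPRVW
>scaffold_T synthetic NRPS domain scaffold
SLWRYKRGKDLEGRDDLTKYALETSDLGCISSLKKDKLQPPGGIQPEAAVEFRTLGDAGC
AASLFAVIDEAIPDKVGTEDKGVKG
>scaffold_E synthetic NRPS domain scaffold
QYGGATVVVQHALEPLEKVGQQIGDHKVELDSFWRNKMELNVLPPAPNGVRLDLLEHTEE
SLDDKSFQIYKYTLLGFALYSVNKLIALTAKMVTNLVVSKLFRHNNSAFDHTNVPAYLAM
PRKEMIQGYDIFGITKLGIQERLVTKLALQKNGMYIYRPAGDAHTAKQLPLAAEVMLFQF
ARLYGTTDAVKISIEYLIEPGLFVSTKDLVLVLNVDEPQQLIGDSAILAADEEVSGSEGL
TIVRSRASREVMQEELYGLDTEEGRVYALPSDAYGAVGSTIREDSAASKVARKEALFLYL
VFAQPMGHFKGESIKLDANAFKWSAHETALESAALDVASKQQQGTFQCADFSAASSDIIP
GAAERDIATSDLTLPMGEKAMEFQESEPLYLTRLDIKDLVISRMINIYLEACAIGPMVNN
AADHPIFETD
>scaffold_TE synthetic NRPS domain scaffold
HGEGLLHLADIEENSAISSAAHIFGQGHSSCLKASYQLVIYLSPTLKDTSIEQVLPPTNR
TAMGALTICIGSTDGSVNSDLRQVGSEGASNVERSIFKIVPRGSSLKGFFHSTLHLYIVI
EFNQFGFPYEVHQMAAPSYRALNMFECTEYGSAAANYTINIIKVQGYSVLNARSEQHKMA
SGMKEASTFKGENWLMNCEYFHSKIIVNNKSIDQAGSMTRWLYSISFPLSFIQKRGETKF
PKDYF
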