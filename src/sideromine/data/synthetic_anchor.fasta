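>synthetic_phe_adomain synthetic reference A-domain scaffold (Phe signature DAWTIAAICK planted at canonical pocket positions)
GRGIRTEVDPSEMNAESANRYKMRNSGTGLETKAGCTNQAQDFDESTTDSSDVCKPIVEI
GSDKENQVLEIENPSRLKACLLNRKVPGMAVKAVGDDVQSPAYLFEFEMTRDTFVGISLL
SKWGSVYGFAIKPGSLNMRAVNLEISGTDCGLLAKQRPVDDRADGELAADCGVAVEESKS
HAKLWWIAPLDDFAHRELGAGVYRLKNDNGLEDDSSFTPPTSVPKTRCTPIICTDAVPWA
ATPLLKVEHATVIAEQTTFAEVLAIKMTLICPLYAPDTLFGYEFPETLEGVIEDESGMIL
AYRYTNGEKFLRTQIKMLGAAAISYFMRLICYDEEYQDLLMVVNSSYAVLELIEPFLAHD
ITTPLIDVRKLISKRETVTVVCSPLSARGVSIFFLLFIRPTIPQYGQLRLQHYNIGEEFY
LNEAKPWRNAVVHVAKYDGHNAIMTLDEEKYKIRRFSVISRPKVAELPTGVLDGLGPWVR
PEETGDKGGFVTWLYLPTLAVSDRALEGHVVEPHKAKPEFAGAGITRKDE
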