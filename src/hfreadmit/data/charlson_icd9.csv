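category,icd9_prefix,weight
MyocardialInfarction,410,1
MyocardialInfarction,412,1
CongestiveHeartFailure,39891,1
CongestiveHeartFailure,40201,1
CongestiveHeartFailure,40211,1
CongestiveHeartFailure,40291,1
CongestiveHeartFailure,40401,1
CongestiveHeartFailure,40403,1
CongestiveHeartFailure,40411,1
CongestiveHeartFailure,40413,1
CongestiveHeartFailure,40491,1
CongestiveHeartFailure,40493,1
CongestiveHeartFailure,4254,1
CongestiveHeartFailure,4255,1
CongestiveHeartFailure,4256,1
CongestiveHeartFailure,4257,1
CongestiveHeartFailure,4258,1
CongestiveHeartFailure,4259,1
CongestiveHeartFailure,428,1
PeripheralVascular,0930,1
PeripheralVascular,4373,1
PeripheralVascular,440,1
PeripheralVascular,441,1
PeripheralVascular,4431,1
PeripheralVascular,4432,1
PeripheralVascular,4433,1
PeripheralVascular,4434,1
PeripheralVascular,4435,1
PeripheralVascular,4436,1
PeripheralVascular,4437,1
PeripheralVascular,4438,1
PeripheralVascular,4439,1
PeripheralVascular,4471,1
PeripheralVascular,5571,1
PeripheralVascular,5579,1
PeripheralVascular,V434,1
Cerebrovascular,36234,1
Cerebrovascular,430,1
Cerebrovascular,431,1
Cerebrovascular,432,1
Cerebrovascular,433,1
Cerebrovascular,434,1
Cerebrovascular,435,1
Cerebrovascular,436,1
Cerebrovascular,437,1
Cerebrovascular,438,1
Dementia,290,1
Dementia,2941,1
Dementia,3312,1
ChronicPulmonary,4168,1
ChronicPulmonary,4169,1
ChronicPulmonary,490,1
ChronicPulmonary,491,1
ChronicPulmonary,492,1
ChronicPulmonary,493,1
ChronicPulmonary,494,1
ChronicPulmonary,495,1
ChronicPulmonary,496,1
ChronicPulmonary,497,1
ChronicPulmonary,498,1
ChronicPulmonary,499,1
ChronicPulmonary,500,1
ChronicPulmonary,501,1
ChronicPulmonary,502,1
ChronicPulmonary,503,1
ChronicPulmonary,504,1
ChronicPulmonary,505,1
ChronicPulmonary,5064,1
ChronicPulmonary,5081,1
ChronicPulmonary,5088,1
Rheumatic,4465,1
Rheumatic,7100,1
Rheumatic,7101,1
Rheumatic,7102,1
Rheumatic,7103,1
Rheumatic,7104,1
Rheumatic,7140,1
Rheumatic,7141,1
Rheumatic,7142,1
Rheumatic,7148,1
Rheumatic,725,1
PepticUlcer,531,1
PepticUlcer,532,1
PepticUlcer,533,1
PepticUlcer,534,1
MildLiverDisease,07022,1
MildLiverDisease,07023,1
MildLiverDisease,07032,1
MildLiverDisease,07033,1
MildLiverDisease,07044,1
MildLiverDisease,07054,1
MildLiverDisease,0706,1
MildLiverDisease,0709,1
MildLiverDisease,570,1
MildLiverDisease,571,1
MildLiverDisease,5733,1
MildLiverDisease,5734,1
MildLiverDisease,5738,1
MildLiverDisease,5739,1
MildLiverDisease,V427,1
DiabetesUncomplicated,2500,1
DiabetesUncomplicated,2501,1
DiabetesUncomplicated,2502,1
DiabetesUncomplicated,2503,1
DiabetesUncomplicated,2508,1
DiabetesUncomplicated,2509,1
DiabetesComplicated,2504,2
DiabetesComplicated,2505,2
DiabetesComplicated,2506,2
DiabetesComplicated,2507,2
Hemiplegia,3341,2
Hemiplegia,342,2
Hemiplegia,343,2
Hemiplegia,3440,2
Hemiplegia,3441,2
Hemiplegia,3442,2
Hemiplegia,3443,2
Hemiplegia,3444,2
Hemiplegia,3445,2
Hemiplegia,3446,2
Hemiplegia,3449,2
RenalDisease,40301,2
RenalDisease,40311,2
RenalDisease,40391,2
RenalDisease,40402,2
RenalDisease,40403,2
RenalDisease,40412,2
RenalDisease,40413,2
RenalDisease,40492,2
RenalDisease,40493,2
RenalDisease,582,2
RenalDisease,5830,2
RenalDisease,5831,2
RenalDisease,5832,2
RenalDisease,5834,2
RenalDisease,5836,2
RenalDisease,5837,2
RenalDisease,585,2
RenalDisease,586,2
RenalDisease,5880,2
RenalDisease,V420,2
RenalDisease,V451,2
RenalDisease,V56,2
AnyMalignancy,140,2
AnyMalignancy,141,2
AnyMalignancy,142,2
AnyMalignancy,143,2
AnyMalignancy,144,2
AnyMalignancy,145,2
AnyMalignancy,146,2
AnyMalignancy,147,2
AnyMalignancy,148,2
AnyMalignancy,149,2
AnyMalignancy,150,2
AnyMalignancy,151,2
AnyMalignancy,152,2
AnyMalignancy,153,2
AnyMalignancy,154,2
AnyMalignancy,155,2
AnyMalignancy,156,2
AnyMalignancy,157,2
AnyMalignancy,158,2
AnyMalignancy,159,2
AnyMalignancy,160,2
AnyMalignancy,161,2
AnyMalignancy,162,2
AnyMalignancy,163,2
AnyMalignancy,164,2
AnyMalignancy,165,2
AnyMalignancy,166,2
AnyMalignancy,167,2
AnyMalignancy,168,2
AnyMalignancy,169,2
AnyMalignancy,170,2
AnyMalignancy,171,2
AnyMalignancy,172,2
AnyMalignancy,174,2
AnyMalignancy,175,2
AnyMalignancy,176,2
AnyMalignancy,177,2
AnyMalignancy,178,2
AnyMalignancy,179,2
AnyMalignancy,180,2
AnyMalignancy,181,2
AnyMalignancy,182,2
AnyMalignancy,183,2
AnyMalignancy,184,2
AnyMalignancy,185,2
AnyMalignancy,186,2
AnyMalignancy,187,2
AnyMalignancy,188,2
AnyMalignancy,189,2
AnyMalignancy,190,2
AnyMalignancy,191,2
AnyMalignancy,192,2
AnyMalignancy,193,2
AnyMalignancy,194,2
AnyMalignancy,195,2
AnyMalignancy,200,2
AnyMalignancy,201,2
AnyMalignancy,202,2
AnyMalignancy,203,2
AnyMalignancy,204,2
AnyMalignancy,205,2
AnyMalignancy,206,2
AnyMalignancy,207,2
AnyMalignancy,208,2
AnyMalignancy,2386,2
ModerateSevereLiver,4560,3
ModerateSevereLiver,4561,3
ModerateSevereLiver,4562,3
ModerateSevereLiver,5722,3
ModerateSevereLiver,5723,3
ModerateSevereLiver,5724,3
ModerateSevereLiver,5728,3
MetastaticSolidTumor,196,6
MetastaticSolidTumor,197,6
MetastaticSolidTumor,198,6
MetastaticSolidTumor,199,6
AIDSHIV,042,6
AIDSHIV,043,6
AIDSHIV,044,6
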