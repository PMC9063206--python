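group,icd9_prefix,vw_weight
CongestiveHeartFailure,39891,7
CongestiveHeartFailure,40201,7
CongestiveHeartFailure,40211,7
CongestiveHeartFailure,40291,7
CongestiveHeartFailure,40401,7
CongestiveHeartFailure,40403,7
CongestiveHeartFailure,40411,7
CongestiveHeartFailure,40413,7
CongestiveHeartFailure,40491,7
CongestiveHeartFailure,40493,7
CongestiveHeartFailure,4254,7
CongestiveHeartFailure,4255,7
CongestiveHeartFailure,4256,7
CongestiveHeartFailure,4257,7
CongestiveHeartFailure,4258,7
CongestiveHeartFailure,4259,7
CongestiveHeartFailure,428,7
CardiacArrhythmias,4260,5
CardiacArrhythmias,42613,5
CardiacArrhythmias,4267,5
CardiacArrhythmias,4269,5
CardiacArrhythmias,42610,5
CardiacArrhythmias,42612,5
CardiacArrhythmias,4270,5
CardiacArrhythmias,4271,5
CardiacArrhythmias,4272,5
CardiacArrhythmias,4273,5
CardiacArrhythmias,4274,5
CardiacArrhythmias,4276,5
CardiacArrhythmias,4277,5
CardiacArrhythmias,4278,5
CardiacArrhythmias,4279,5
CardiacArrhythmias,7850,5
CardiacArrhythmias,99601,5
CardiacArrhythmias,99604,5
CardiacArrhythmias,V450,5
CardiacArrhythmias,V533,5
ValvularDisease,0932,-1
ValvularDisease,394,-1
ValvularDisease,395,-1
ValvularDisease,396,-1
ValvularDisease,397,-1
ValvularDisease,424,-1
ValvularDisease,7463,-1
ValvularDisease,7464,-1
ValvularDisease,7465,-1
ValvularDisease,7466,-1
ValvularDisease,V422,-1
ValvularDisease,V433,-1
PulmonaryCirculation,4150,4
PulmonaryCirculation,4151,4
PulmonaryCirculation,416,4
PulmonaryCirculation,4170,4
PulmonaryCirculation,4178,4
PulmonaryCirculation,4179,4
PeripheralVascular,0930,2
PeripheralVascular,4373,2
PeripheralVascular,440,2
PeripheralVascular,441,2
PeripheralVascular,4431,2
PeripheralVascular,4432,2
PeripheralVascular,4433,2
PeripheralVascular,4434,2
PeripheralVascular,4435,2
PeripheralVascular,4436,2
PeripheralVascular,4437,2
PeripheralVascular,4438,2
PeripheralVascular,4439,2
PeripheralVascular,4471,2
PeripheralVascular,5571,2
PeripheralVascular,5579,2
PeripheralVascular,V434,2
HypertensionUncomplicated,401,0
HypertensionComplicated,402,0
HypertensionComplicated,403,0
HypertensionComplicated,404,0
HypertensionComplicated,405,0
Paralysis,3341,7
Paralysis,342,7
Paralysis,343,7
Paralysis,3440,7
Paralysis,3441,7
Paralysis,3442,7
Paralysis,3443,7
Paralysis,3444,7
Paralysis,3445,7
Paralysis,3446,7
Paralysis,3449,7
OtherNeurological,3319,6
OtherNeurological,3320,6
OtherNeurological,3321,6
OtherNeurological,3334,6
OtherNeurological,3335,6
OtherNeurological,33392,6
OtherNeurological,334,6
OtherNeurological,335,6
OtherNeurological,3362,6
OtherNeurological,340,6
OtherNeurological,341,6
OtherNeurological,345,6
OtherNeurological,3481,6
OtherNeurological,3483,6
OtherNeurological,7803,6
OtherNeurological,7843,6
ChronicPulmonary,4168,3
ChronicPulmonary,4169,3
ChronicPulmonary,490,3
ChronicPulmonary,491,3
ChronicPulmonary,492,3
ChronicPulmonary,493,3
ChronicPulmonary,494,3
ChronicPulmonary,495,3
ChronicPulmonary,496,3
ChronicPulmonary,500,3
ChronicPulmonary,501,3
ChronicPulmonary,502,3
ChronicPulmonary,503,3
ChronicPulmonary,504,3
ChronicPulmonary,505,3
ChronicPulmonary,5064,3
ChronicPulmonary,5081,3
ChronicPulmonary,5088,3
DiabetesUncomplicated,2500,0
DiabetesUncomplicated,2501,0
DiabetesUncomplicated,2502,0
DiabetesUncomplicated,2503,0
DiabetesComplicated,2504,0
DiabetesComplicated,2505,0
DiabetesComplicated,2506,0
DiabetesComplicated,2507,0
DiabetesComplicated,2508,0
DiabetesComplicated,2509,0
Hypothyroidism,2409,0
Hypothyroidism,243,0
Hypothyroidism,244,0
Hypothyroidism,2461,0
Hypothyroidism,2468,0
RenalFailure,40301,5
RenalFailure,40311,5
RenalFailure,40391,5
RenalFailure,40402,5
RenalFailure,40403,5
RenalFailure,40412,5
RenalFailure,40413,5
RenalFailure,40492,5
RenalFailure,40493,5
RenalFailure,585,5
RenalFailure,586,5
RenalFailure,5880,5
RenalFailure,V420,5
RenalFailure,V451,5
RenalFailure,V56,5
LiverDisease,07022,11
LiverDisease,07023,11
LiverDisease,07032,11
LiverDisease,07033,11
LiverDisease,07044,11
LiverDisease,07054,11
LiverDisease,0706,11
LiverDisease,0709,11
LiverDisease,4560,11
LiverDisease,4561,11
LiverDisease,4562,11
LiverDisease,570,11
LiverDisease,571,11
LiverDisease,5722,11
LiverDisease,5723,11
LiverDisease,5724,11
LiverDisease,5728,11
LiverDisease,5733,11
LiverDisease,5734,11
LiverDisease,5738,11
LiverDisease,5739,11
LiverDisease,V427,11
PepticUlcer,5317,0
PepticUlcer,5319,0
PepticUlcer,5327,0
PepticUlcer,5329,0
PepticUlcer,5337,0
PepticUlcer,5339,0
PepticUlcer,5347,0
PepticUlcer,5349,0
AIDSHIV,042,0
AIDSHIV,043,0
AIDSHIV,044,0
Lymphoma,200,9
Lymphoma,201,9
Lymphoma,202,9
Lymphoma,2030,9
Lymphoma,2386,9
MetastaticCancer,196,12
MetastaticCancer,197,12
MetastaticCancer,198,12
MetastaticCancer,199,12
SolidTumor,140,4
SolidTumor,141,4
SolidTumor,142,4
SolidTumor,143,4
SolidTumor,144,4
SolidTumor,145,4
SolidTumor,146,4
SolidTumor,147,4
SolidTumor,148,4
SolidTumor,149,4
SolidTumor,150,4
SolidTumor,151,4
SolidTumor,152,4
SolidTumor,153,4
SolidTumor,154,4
SolidTumor,155,4
SolidTumor,156,4
SolidTumor,157,4
SolidTumor,158,4
SolidTumor,159,4
SolidTumor,160,4
SolidTumor,161,4
SolidTumor,162,4
SolidTumor,163,4
SolidTumor,164,4
SolidTumor,165,4
SolidTumor,166,4
SolidTumor,167,4
SolidTumor,168,4
SolidTumor,169,4
SolidTumor,170,4
SolidTumor,171,4
SolidTumor,172,4
SolidTumor,174,4
SolidTumor,175,4
SolidTumor,176,4
SolidTumor,177,4
SolidTumor,178,4
SolidTumor,179,4
SolidTumor,180,4
SolidTumor,181,4
SolidTumor,182,4
SolidTumor,183,4
SolidTumor,184,4
SolidTumor,185,4
SolidTumor,186,4
SolidTumor,187,4
SolidTumor,188,4
SolidTumor,189,4
SolidTumor,190,4
SolidTumor,191,4
SolidTumor,192,4
SolidTumor,193,4
SolidTumor,194,4
SolidTumor,195,4
RheumatoidArthritis,446,0
RheumatoidArthritis,7010,0
RheumatoidArthritis,7100,0
RheumatoidArthritis,7101,0
RheumatoidArthritis,7102,0
RheumatoidArthritis,7103,0
RheumatoidArthritis,7104,0
RheumatoidArthritis,7108,0
RheumatoidArthritis,7109,0
RheumatoidArthritis,7112,0
RheumatoidArthritis,714,0
RheumatoidArthritis,7193,0
RheumatoidArthritis,720,0
RheumatoidArthritis,725,0
RheumatoidArthritis,7285,0
RheumatoidArthritis,72889,0
RheumatoidArthritis,72930,0
Coagulopathy,286,3
Coagulopathy,2871,3
Coagulopathy,2873,3
Coagulopathy,2874,3
Coagulopathy,2875,3
Obesity,2780,-4
WeightLoss,260,6
WeightLoss,261,6
WeightLoss,262,6
WeightLoss,263,6
WeightLoss,7832,6
WeightLoss,7994,6
FluidElectrolyte,2536,5
FluidElectrolyte,276,5
BloodLossAnemia,2800,-2
DeficiencyAnemia,2801,-2
DeficiencyAnemia,2808,-2
DeficiencyAnemia,2809,-2
DeficiencyAnemia,281,-2
AlcoholAbuse,2652,0
AlcoholAbuse,2911,0
AlcoholAbuse,2912,0
AlcoholAbuse,2913,0
AlcoholAbuse,2915,0
AlcoholAbuse,2918,0
AlcoholAbuse,2919,0
AlcoholAbuse,30390,0
AlcoholAbuse,30393,0
AlcoholAbuse,30500,0
AlcoholAbuse,30503,0
AlcoholAbuse,3575,0
AlcoholAbuse,5353,0
AlcoholAbuse,5710,0
AlcoholAbuse,5711,0
AlcoholAbuse,5712,0
AlcoholAbuse,5713,0
AlcoholAbuse,980,0
AlcoholAbuse,V113,0
DrugAbuse,292,-7
DrugAbuse,304,-7
DrugAbuse,30520,-7
DrugAbuse,30530,-7
DrugAbuse,30540,-7
DrugAbuse,30550,-7
DrugAbuse,30560,-7
DrugAbuse,30570,-7
DrugAbuse,30580,-7
DrugAbuse,30590,-7
Psychoses,2938,0
Psychoses,295,0
Psychoses,29604,0
Psychoses,29614,0
Psychoses,29644,0
Psychoses,29654,0
Psychoses,297,0
Psychoses,298,0
Depression,2962,-3
Depression,2963,-3
Depression,2965,-3
Depression,3004,-3
Depression,309,-3
Depression,311,-3
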