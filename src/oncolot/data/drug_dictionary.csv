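drug_code,generic_name,drug_class,substitution_group,maintenance_eligible,default_runout_days
J9271,pembrolizumab,ICI,,true,21
J9299,nivolumab,ICI,,true,21
J9228,ipilimumab,ICI,,true,21
J9022,atezolizumab,ICI,,true,21
J9173,durvalumab,ICI,,true,21
J9119,cemiplimab,ICI,,true,21
J9060,cisplatin,PLATINUM,platinum_agent,false,21
J9045,carboplatin,PLATINUM,platinum_agent,false,21
J9263,oxaliplatin,PLATINUM,,false,21
J9267,paclitaxel,NONPLAT_CHEMO,paclitaxel_taxane,false,21
J9264,nab-paclitaxel,NONPLAT_CHEMO,paclitaxel_taxane,false,21
J9171,docetaxel,NONPLAT_CHEMO,,false,21
J9305,pemetrexed,NONPLAT_CHEMO,,true,21
J9201,gemcitabine,NONPLAT_CHEMO,,false,21
J9390,vinorelbine,NONPLAT_CHEMO,,false,21
J9181,etoposide,NONPLAT_CHEMO,,false,21
J8560,etoposide-oral,NONPLAT_CHEMO,,false,21
J9351,topotecan,SCLC_TYPICAL,,false,21
J9223,lurbinectedin,SCLC_TYPICAL,,false,21
J9035,bevacizumab,VEGF,,true,21
J9308,ramucirumab,VEGF,,true,21
00310155030,osimertinib,TARGETED,,false,30
50242013001,alectinib,TARGETED,,false,30
55150039201,sotorasib,TARGETED,,false,30
50242006201,erlotinib,TARGETED,,false,30
63459017560,crizotinib,TARGETED,,false,30
00069022730,lorlatinib,TARGETED,,false,30
00597013730,afatinib,TARGETED,,false,30
00310048230,gefitinib,TARGETED,,false,30
00069119701,dacomitinib,TARGETED,,false,30
63402030230,brigatinib,TARGETED,,false,30
00078070987,capmatinib,TARGETED,,false,30
00024586001,larotrectinib,TARGETED,,false,30
00310155599,selpercatinib,TARGETED,,false,30
00071015523,atorvastatin,OTHER,,false,30
00143126901,lisinopril,OTHER,,false,30
00093104801,metformin,OTHER,,false,30
00186077631,omeprazole,OTHER,,false,30
00173068220,albuterol,OTHER,,false,30
00406055201,oxycodone,OTHER,,false,30
00781547164,ondansetron,OTHER,,false,30
63323018810,dexamethasone,OTHER,,false,30
61703034018,filgrastim,OTHER,,false,21
00054418425,warfarin,OTHER,,false,30
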