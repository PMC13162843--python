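patient_id,sex,age,cancer,treatment,biopsy,pre_blood,blood_1mo,blood_3mo
TCR2,female,60,GIST liver met,Cryoablation,1,1,1,1
TCR4,male,67,Leiomyosarcoma liver met,HAE,1,1,1,1
TCR5,female,77,Leiomyosarcoma liver met,HAE,0,1,1,1
TCR6,male,70,ICC,Mapping,0,1,1,0
TCR7,male,66,Melanoma liver met,HAE,1,1,1,1
TCR9,male,48,GIST liver met,HAE,0,1,0,1
TCR11,male,51,GIST liver met,HAE,0,1,1,0
TCR12,male,84,Melanoma liver met,HAE,1,1,1,1
TCR13,female,34,Melanoma liver met,MWA,1,1,1,1
TCR14,female,75,Melanoma liver met,HAE,1,1,1,1
TCR18,male,57,Leiomyosarcoma liver met,HAE,0,1,1,0
TCR22,male,56,Liposarcoma liver met,MWA,0,1,1,1
TCR24,female,76,GIST liver met,HAE,0,1,0,1
TCR27,male,90,Melanoma liver met,HAE,1,1,1,0
TCR28,male,41,None,Control,0,1,1,0
TCR31,female,76,Melanoma liver met,Y90,0,1,1,1
TCR34,male,81,Melanoma liver met,Y90,1,1,1,0
TCR35,male,77,Melanoma liver met,HAE,0,1,1,0
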