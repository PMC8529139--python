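study_id,article_id,year,country,ethnicity_group,cancer_label,cancer_group,pancreatic,sample_source,sample_group,tp,fn,fp,tn,sample_size
Akers2013,Akers2013,2013,United States,caucasian,Glioma,other,False,CSF-EV,other,11,2,0,14,27
Ando2019,Ando2019,2019,Japan,asian,BC,breast,False,urine,other,16,6,5,21,48
Butz2015,Butz2015,2015,Canada,caucasian,RCC,other,False,urine,other,20,8,4,14,46
Goto2018-IPMN,Goto2018,2018,Japan,asian,IPMN,other,True,serum,serum,22,7,4,18,51
Goto2018-PCearly,Goto2018,2018,Japan,asian,PC,digestive,True,serum,serum,6,3,4,18,31
Goto2018-PCadv,Goto2018,2018,Japan,asian,PC,digestive,True,serum,serum,20,3,4,18,45
HernandezWalias2020,HernandezWalias2020,2020,Spain,caucasian,Lymphoma,other,False,plasma,plasma,25,12,21,53,111
Jin2019,Jin2019,2019,China,asian,CRC,digestive,False,serum,serum,11,0,14,18,43
Kawamura2018-PV,Kawamura2018,2018,Japan,asian,PC,digestive,True,portal vein blood,other,24,9,6,16,55
Kawamura2018-PB,Kawamura2018,2018,Japan,asian,PC,digestive,True,peripheral blood,other,18,15,8,14,55
Lai2017,Lai2017,2017,United States,caucasian,PC,digestive,True,plasma,plasma,29,0,0,6,35
Liu2014,Liu2014,2014,China,asian,Glioma,other,False,CLF exosome,other,40,5,0,25,70
Liu2020-a,Liu2020,2020,United States,caucasian,LC,lung,False,serum,serum,53,11,2,13,79
Liu2020-b,Liu2020,2020,United States,caucasian,LC,lung,False,serum,serum,29,35,3,12,79
Matsuzaki2017,Matsuzaki2017,2017,Japan,asian,UC,other,False,urine,other,27,9,1,23,60
Melo2014,Melo2014,2014,United States,caucasian,BC,breast,False,serum,serum,9,2,0,8,19
Nakamura2019,Nakamura2019,2019,Japan,asian,PDAC,digestive,True,pancreatic juice,other,22,5,1,7,35
OgataKawata2014,OgataKawata2014,2014,Japan,asian,CC,other,False,serum,serum,54,34,2,9,99
Pan2018,Pan2018,2018,Germany,caucasian,OC,other,False,plasma,plasma,65,41,5,24,135
Que2013,Que2013,2013,China,asian,PC,digestive,True,serum,serum,21,1,5,22,49
Soeda2019,Soeda2019,2019,Japan,asian,GC,digestive,False,plasma,plasma,45,28,13,43,129
Tanaka2013,Tanaka2013,2013,Japan,asian,ESCC,digestive,False,serum,serum,28,16,6,35,85
Taylor2008,Taylor2008,2008,United States,caucasian,CRC,digestive,False,serum,serum,30,0,0,10,40
Tokuhisa2015,Tokuhisa2015,2015,Japan,asian,HCC,other,False,PLF exosome,other,8,1,2,7,18
Tsukamoto2017,Tsukamoto2017,2017,Japan,asian,CRC,digestive,False,plasma,plasma,78,72,72,104,326
Uratani2016,Uratani2016,2016,Japan,asian,CRC,digestive,False,serum,serum,18,8,9,38,73
Wang2014,Wang2014,2014,China,asian,CRC,digestive,False,serum,serum,9,4,12,18,43
Wang2020,Wang2020,2020,China,asian,HCC,other,False,plasma,plasma,41,9,4,46,100
WangJ2014,WangJ2014,2014,China,asian,LSCC,other,False,serum,serum,36,16,9,40,101
Yang2020,Yang2020,2020,China,asian,LC,lung,False,serum,serum,61,14,7,17,99
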