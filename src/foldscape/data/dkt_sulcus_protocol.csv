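label_a,label_b,sulcus_id,name,hemisphere
1012,1027,0,frontomarginal sulcus,left
2012,2027,0,frontomarginal sulcus,right
1027,1028,1,superior frontal sulcus,left
2027,2028,1,superior frontal sulcus,right
1003,1028,1,superior frontal sulcus,left
2003,2028,1,superior frontal sulcus,right
1019,1027,2,inferior frontal sulcus,left
2019,2027,2,inferior frontal sulcus,right
1020,1027,2,inferior frontal sulcus,left
2020,2027,2,inferior frontal sulcus,right
1003,1020,2,inferior frontal sulcus,left
2003,2020,2,inferior frontal sulcus,right
1003,1018,2,inferior frontal sulcus,left
2003,2018,2,inferior frontal sulcus,right
1003,1024,3,precentral sulcus,left
2003,2024,3,precentral sulcus,right
1018,1024,3,precentral sulcus,left
2018,2024,3,precentral sulcus,right
1024,1028,3,precentral sulcus,left
2024,2028,3,precentral sulcus,right
1022,1024,4,central sulcus,left
2022,2024,4,central sulcus,right
1022,1031,5,postcentral sulcus,left
2022,2031,5,postcentral sulcus,right
1022,1029,5,postcentral sulcus,left
2022,2029,5,postcentral sulcus,right
1008,1022,5,postcentral sulcus,left
2008,2022,5,postcentral sulcus,right
1029,1031,6,intraparietal sulcus,left
2029,2031,6,intraparietal sulcus,right
1008,1029,6,intraparietal sulcus,left
2008,2029,6,intraparietal sulcus,right
1008,1031,7,primary intermediate sulcus,left
2008,2031,7,primary intermediate sulcus,right
1030,1031,8,sylvian fissure,left
2030,2031,8,sylvian fissure,right
1018,1030,8,sylvian fissure,left
2018,2030,8,sylvian fissure,right
1020,1030,8,sylvian fissure,left
2020,2030,8,sylvian fissure,right
1019,1030,8,sylvian fissure,left
2019,2030,8,sylvian fissure,right
1012,1030,8,sylvian fissure,left
2012,2030,8,sylvian fissure,right
1030,1035,9,circular insular sulcus,left
2030,2035,9,circular insular sulcus,right
1031,1035,9,circular insular sulcus,left
2031,2035,9,circular insular sulcus,right
1018,1035,9,circular insular sulcus,left
2018,2035,9,circular insular sulcus,right
1020,1035,9,circular insular sulcus,left
2020,2035,9,circular insular sulcus,right
1019,1035,9,circular insular sulcus,left
2019,2035,9,circular insular sulcus,right
1012,1035,9,circular insular sulcus,left
2012,2035,9,circular insular sulcus,right
1024,1035,9,circular insular sulcus,left
2024,2035,9,circular insular sulcus,right
1022,1035,9,circular insular sulcus,left
2022,2035,9,circular insular sulcus,right
1034,1035,9,circular insular sulcus,left
2034,2035,9,circular insular sulcus,right
1015,1035,9,circular insular sulcus,left
2015,2035,9,circular insular sulcus,right
1015,1030,10,superior temporal sulcus,left
2015,2030,10,superior temporal sulcus,right
1009,1015,11,inferior temporal sulcus,left
2009,2015,11,inferior temporal sulcus,right
1007,1009,12,occipitotemporal sulcus,left
2007,2009,12,occipitotemporal sulcus,right
1007,1011,12,occipitotemporal sulcus,left
2007,2011,12,occipitotemporal sulcus,right
1007,1016,13,collateral sulcus,left
2007,2016,13,collateral sulcus,right
1007,1013,13,collateral sulcus,left
2007,2013,13,collateral sulcus,right
1006,1007,13,collateral sulcus,left
2006,2007,13,collateral sulcus,right
1030,1034,14,transverse temporal sulcus,left
2030,2034,14,transverse temporal sulcus,right
1002,1028,15,cingulate sulcus,left
2002,2028,15,cingulate sulcus,right
1026,1028,15,cingulate sulcus,left
2026,2028,15,cingulate sulcus,right
1014,1026,15,cingulate sulcus,left
2014,2026,15,cingulate sulcus,right
1017,1023,15,cingulate sulcus,left
2017,2023,15,cingulate sulcus,right
1002,1017,15,cingulate sulcus,left
2002,2017,15,cingulate sulcus,right
1017,1028,16,paracentral sulcus,left
2017,2028,16,paracentral sulcus,right
1005,1025,17,parieto-occipital sulcus,left
2005,2025,17,parieto-occipital sulcus,right
1021,1025,17,parieto-occipital sulcus,left
2021,2025,17,parieto-occipital sulcus,right
1005,1021,18,calcarine sulcus,left
2005,2021,18,calcarine sulcus,right
1013,1021,18,calcarine sulcus,left
2013,2021,18,calcarine sulcus,right
1014,1028,19,superior rostral sulcus,left
2014,2028,19,superior rostral sulcus,right
1023,1025,20,subparietal sulcus,left
2023,2025,20,subparietal sulcus,right
1010,1025,20,subparietal sulcus,left
2010,2025,20,subparietal sulcus,right
1012,1014,21,olfactory sulcus,left
2012,2014,21,olfactory sulcus,right
1008,1011,22,lateral occipital sulcus,left
2008,2011,22,lateral occipital sulcus,right
1011,1015,22,lateral occipital sulcus,left
2011,2015,22,lateral occipital sulcus,right
1009,1011,22,lateral occipital sulcus,left
2009,2011,22,lateral occipital sulcus,right
1006,1016,23,rhinal sulcus,left
2006,2016,23,rhinal sulcus,right
1006,1009,23,rhinal sulcus,left
2006,2009,23,rhinal sulcus,right
1013,1016,24,medial occipital sulcus,left
2013,2016,24,medial occipital sulcus,right
1010,1013,24,medial occipital sulcus,left
2010,2013,24,medial occipital sulcus,right
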