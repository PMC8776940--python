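row_type,governorate,oc_pct,iud_pct,condom_pct,injectable_3m_pct,implant_pct,injectable_1m_pct,users_total,oc_count,iud_count,condom_count,injectable_3m_count,implant_count,injectable_1m_count,note
governorate,Cairo,42,14,7,29,0.5,3.5,708152,,,,,,,
governorate,Alexandria,35,14,8,35,0.4,2.4,361784,,,,,,,
governorate,Port-Said,36,9,12,42,0.3,0,77908,,,,,,,
governorate,Suez,54,9,3,25,0.6,0,71036,,,,,,,
region,Urban Governorates,39,17,7,34,0.6,2.8,1218880,,,,,,,
governorate,Damietta,61,6,4,22,0.2,0.0,207108,,,,,,,
governorate,Kafr-Elsheikh,47,6,1,39,0.2,0.0,492016,,,,,,,
governorate,Gharbia,57,9,2,24,0.2,0.0,647728,,,,,,,
governorate,Dakahlia,48,9,2,34,0.2,0.0,978268,,,,,,,
governorate,Qalubia,50,8,2,33,0.2,0.0,772504,,,,,,,
governorate,Menofia,62,5,1,24,0.1,4.4,813220,,,,,,,
governorate,Behera,47,9,1,32,0.1,0.0,1098520,,,,,,,
governorate,Ismailia,48,6,2,36,0.1,0.0,206468,,,,,,,
governorate,Sharkia,66,3,1,23,0.1,5.4,1699280,,,,,,,
region,Lower Egypt Governorates,55,9,1.8,33,0.2,1.9,6915112,,,,,,,
governorate,Aswan,75,2,1,16,0.3,0.0,286260,,,,,,,
governorate,Giza,56,10,1,28,0.1,0.2,998424,,,,,,,
governorate,Luxor,79,1,1,12,0.3,0.0,300964,,,,,,,
governorate,Quena,73,1,1,25,0.3,0.0,516988,,,,,,,
governorate,Fayoum,37,6,1,51,0.4,2.9,578980,,,,,,,
governorate,Beni-Suef,42,7,0.5,41,0.2,4.8,498612,,,,,,,
governorate,Souhag,59,3,1,31,0.2,0.7,553064,,,,,,,
governorate,Minia,48,4,1,42,0.2,0.8,1096052,,,,,,,
governorate,Asuit,54,5,1,32,0.2,5.6,529608,,,,,,,
region,Upper Egypt Governorates,54,7,0.9,36,0.2,1.6,5358952,,,,,,,
governorate,Red Sea,70,4,3,16,0.3,0,44420,,,,,,,
governorate,New Valley,68,5,2,20,0.4,0,41108,,,,,,,
governorate,Matrouh,43,5,2,48,0.6,0,43336,,,,,,,
governorate,N. Sinai,62,5,0.5,32,0.6,0,31724,,,,,,,
governorate,S. Sinai,75,2,3,20,1.1,0,16572,,,,,,,
region,Frontier Governorates,64,6,2.1,25,0.3,0,177160,,,,,,,
national,Total Egypt,54,7,2,31,0.2,6,13670104,7376884,903636,255016,4228168,27388,879012,
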