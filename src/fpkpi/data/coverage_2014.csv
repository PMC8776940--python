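row_type,governorate,mwra_share_pct,clinic_share_pct,clinics_per_10k_mwra,ccr_pct,mwra_count,clinics_count,note
governorate,Cairo,10,4.7,1.8,33,,,
governorate,Alexandria,5,3.1,2.2,33,,,
governorate,Port-Said,1,0.6,3,30,,,
governorate,Suez,1,0.6,3.2,31,,,
region,Urban Governorates,17,9,2.6,32,,,
governorate,Damietta,2,1.8,4.4,32,,,
governorate,Kafr-Elsheikh,4,4.7,5,36,,,
governorate,Gharbia,5,5.3,3.8,43,,,
governorate,Dakahlia,7,9,5,46,,,
governorate,Qalubia,5,3.6,2.3,40,,,
governorate,Menofia,5,4.5,3.8,41,,,
governorate,Behera,7,7.9,4.7,57,,,
governorate,Ismailia,1,1.3,3.7,45,,,
governorate,Sharkia,8,8.6,4.3,40,,,
region,Lower Egypt Governorates,44,46.7,4.1,42.2,,,
governorate,Aswan,2,3.9,9.6,26,,,
governorate,Giza,9,4.5,1.9,36,,,
governorate,Luxor,1,2,5.9,24,,,
governorate,Quena,3,4.4,5,19,,,
governorate,Fayoum,4,3,3,40,,,
governorate,Beni-Suef,3,3.5,4,43,,,
governorate,Souhag,5,6.2,4.5,19,,,
governorate,Minia,6,6.7,4.4,47,,,
governorate,Asuit,5,4.8,3.9,28,,,
region,Upper Egypt Governorates,38,39.0,4.7,31.3,,,
governorate,Red Sea,0.4,0.7,6.7,25,,,
governorate,New Valley,0.3,1.1,16.4,37,,,
governorate,Matrouh,0.4,1.2,10.4,26,,,
governorate,N. Sinai,0.5,1.6,12.5,17,,,
governorate,S. Sinai,0.1,0.8,28.2,23,,,MWRA share printed as 'o.1'; recorded as the corrected value 0.1
region,Frontier Governorates,1.6,5.4,14.84,25.6,,,
national,Total Egypt,,,3.8,37,15799805,6038,
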