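row_type,governorate,first_visit_pct,new_clients_pct,get_method_pct,counseling_pct,rh_services_pct,side_effects_pct,note
governorate,Cairo,34,15,,,11.3,18.9,get-method/counseling cells ambiguous under printed column concatenation; left unparsed
governorate,Alexandria,35,15,85,3.1,11.5,14.6,
governorate,Port-Said,28,10,71,22.2,6.8,28.9,
governorate,Suez,33,10,67,27.1,6.3,33.4,
region,Urban Governorates,34,14,81,8.8,10.7,19.5,
governorate,Damietta,18,8,88,2.9,8.8,22.2,
governorate,Kafr-Elsheikh,19,9,84,10.9,4.7,35.5,
governorate,Gharbia,19,10,64,27.2,8.3,38.1,
governorate,Dakahlia,23,11,78,18.2,4.0,18.3,
governorate,Qalubia,22,11,92,3.4,5.1,15.6,
governorate,Menofia,15,7,62,35.4,2.7,6.3,
governorate,Behera,22,9,94,0.2,6.0,25.9,
governorate,Ismailia,22,9,74,17.8,8.1,21.3,
governorate,Sharkia,16,8,82,12.7,5.6,8.5,
region,Lower Egypt Governorates,19,9,79,15.9,5.4,21.3,
governorate,Aswan,17,9,81,15.7,3.8,18.4,
governorate,Giza,28,14,81,12.3,6.9,12.6,
governorate,Luxor,13,5,82,14.6,3.7,19.5,
governorate,Quena,14,9,96,0.3,3.6,18.3,
governorate,Fayoum,23,13,55,42.0,3.0,3.4,
governorate,Beni-Suef,28,15,87,4.8,7.8,45.0,
governorate,Souhag,23,16,75,20.1,4.9,3.9,
governorate,Minia,23,12,97,0.9,2.5,8.0,
governorate,Asuit,16,12,92,3.2,4.8,25.0,
region,Upper Egypt Governorates,22,12,82,13.8,4.5,18.4,
governorate,Red Sea,18,5,85,8.4,6.4,14.7,
governorate,New Valley,14,6,69,27.9,3.6,31.4,
governorate,Matrouh,33,20,97,0.1,3.4,3.5,
governorate,N. Sinai,23,21,94,1.1,4.9,6.1,
governorate,S. Sinai,20,12,76,11.8,12.1,23.9,
region,Frontier Governorates,22,13,83,11.4,5.3,16.7,
national,Total Egypt,21,11,83,14.4,5.6,19.9,
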