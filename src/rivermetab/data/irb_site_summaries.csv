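# Published site-level metabolism summaries for the 17 Illinois River Basin
# monitoring sites, USGS data release 10.5066/P9TEBOUR (CC0).
# Units: discharge m3/s; GPP, ER, NEP g O2 m-2 d-1; percentages in percent.
site_id,site_name,group,n_days_unflagged,pct_unflagged,mean_discharge,sd_discharge,mean_gpp,sd_gpp,mean_er,sd_er,mean_nep,pct_autotrophic,depth_method,overall_confidence
05586300,ILLINOIS RIVER AT FLORENCE IL,illinois,1888,73,892.1,670.4,2.22,2.28,-6.14,4.37,-3.92,14,rating,LOW
05558300,ILLINOIS RIVER AT HENRY IL,illinois,444,68,532.0,423.3,2.41,2.29,-7.44,4.55,-4.98,22,hydraulic,HIGH
05553700,ILLINOIS RIVER AT STARVED ROCK IL,illinois,398,59,348.4,327.3,4.87,4.33,-5.17,4.82,-0.30,56,hydraulic,MEDIUM
05543010,ILLINOIS RIVER AT SENECA IL,illinois,337,32,353.2,293.4,4.14,3.49,-8.01,6.06,-3.87,39,rating,MEDIUM
05549500,FOX RIVER NEAR MCHENRY IL,fox,351,95,123.6,12.8,8.64,5.04,-7.79,4.22,0.85,47,rating,LOW
05550001,FOX RIVER AT ALGONQUIN IL,fox,351,84,47.1,42.1,5.62,3.01,-6.83,4.19,-1.21,38,rating,MEDIUM
05537980,DES PLAINES RIVER AT ROUTE 53 AT JOLIET IL,des_plaines,767,75,135.7,92.6,3.76,2.07,-8.78,2.21,-5.02,5,rating,MEDIUM
05538010,DES PLAINES RIVER AT ROCKDALE IL,des_plaines,174,42,118.4,67.4,0.70,1.15,-7.57,3.76,-6.87,1,hydraulic,MEDIUM
05538020,DES PLAINES RIVER IN LOCK CHANNEL AT ROCKDALE IL,des_plaines,266,44,24.9,66.8,1.09,0.99,-4.41,3.39,-3.32,10,hydraulic,MEDIUM
05518000,KANKAKEE RIVER AT SHELBY IN,kankakee,1325,89,61.2,29.4,0.45,0.69,-3.78,2.28,-3.35,1,rating,HIGH
05517500,KANKAKEE RIVER AT DUNNS BRIDGE IN,kankakee,556,96,47.2,25.7,0.59,0.51,-4.23,1.90,-3.65,2,rating,HIGH
05515500,KANKAKEE RIVER AT DAVIS IN,kankakee,1630,88,19.6,8.2,1.01,0.85,-5.42,2.11,-4.41,0,rating,HIGH
05524500,IROQUOIS RIVER NEAR FORESMAN IN,tributary,439,83,12.4,13.8,2.47,3.56,-5.79,3.84,-3.32,16,rating,HIGH
05536356,GRAND CALUMET RIVER AT COLUMBIA AV AT HAMMOND IN,tributary,167,94,4.2,0.7,1.64,0.79,-2.56,0.96,-0.92,16,hydraulic,HIGH
05576100,LICK CREEK NEAR WOODSIDE IL,tributary,453,67,1.3,2.5,2.67,3.03,-7.84,3.39,-5.17,12,rating,LOW
05576195,SUGAR CREEK NEAR CHATHAM IL,tributary,234,28,1.7,6.1,2.39,2.29,-7.46,4.54,-5.06,18,rating,LOW
05579630,KICKAPOO CREEK NEAR BLOOMINGTON IL,tributary,1158,92,0.4,1.8,2.32,2.35,-3.61,2.85,-1.29,23,rating,HIGH
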