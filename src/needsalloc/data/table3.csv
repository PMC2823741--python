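district,population_2008,normalized_asset_index,weighted_population_asset,weighted_population_stunting,share_asset_pct,share_stunting_pct
Balaka,316748,1.194,378083,361093,1.94,2.31
Blantyre,999491,2.616,2614947,1162408,13.41,7.44
Chikwawa,438895,1.416,621280,513946,3.19,3.29
Chiradzulu,290946,1.328,386520,341862,1.98,2.19
Chitipa,179072,1.101,197101,204858,1.01,1.31
Dedza,623789,1.021,636917,799074,3.27,5.11
Dowa,556678,1.242,691347,668014,3.55,4.27
Karonga,272789,1.479,403586,304978,2.07,1.95
Kasungu,616085,1.210,745753,732525,3.83,4.69
Lilongwe,1897167,1.996,3787212,2325927,19.43,14.88
Machinga,488996,1.095,535673,628849,2.75,4.02
Mangochi,803602,1.255,1008684,963519,5.17,6.16
Mchinji,456558,1.199,547441,594895,2.81,3.81
Mulanje,525429,1.447,760077,634718,3.90,4.06
Mwanza,94476,1.240,117167,109970,0.60,0.70
Mzimba,853305,1.731,1477107,1013726,7.58,6.49
Nkhata Bay,213779,1.371,293108,247129,1.50,1.58
Nkhotakota,301868,1.413,426476,365864,2.19,2.34
Nsanje,238089,1.235,294010,269993,1.51,1.73
Ntcheu,474464,1.115,529115,581693,2.71,3.72
Ntchisi,224098,1.000,224098,289086,1.15,1.85
Phalombe,313227,1.111,347884,386209,1.78,2.47
Rumphi,169112,1.432,242232,189067,1.24,1.21
Salima,340327,1.518,516700,385250,2.65,2.46
Thyolo,587455,1.329,780533,721395,4.00,4.61
Zomba,670533,1.391,932631,835484,4.78,5.34
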