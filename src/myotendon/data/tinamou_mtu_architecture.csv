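# Muscle-tendon unit architecture of the Eudromia elegans hindlimb model (36 actuators).
# Units: mass_g in grams, lengths in mm, pennation_deg in degrees, fmax_N in newtons.
# Values are transcribed as printed; tuned_* columns are the inverse-simulation-tuned values.
# Note: the printed tuned fibre length for ILPOp ("749") is a typo; 74.9 mm is adopted here.
name,abbreviation,mass_g,fibre_length_mm,tuned_fibre_length_mm,slack_length_mm,tuned_slack_length_mm,pennation_deg,fmax_N
Iliotibialis cranialis,IC,2.49,62.2,70.3,3.1,3.1,0,11.324
Iliotibialis lateralis pars preactabularis,ILPR,0.521,28.8,31.2,39,45.2,0,5.118
Iliotibialis lateralis pars postacetabularis (anterior part),ILPOa,2.15,65.4,69.9,2.7,2.7,0,9.814
Iliotibialis lateralis pars postacetabularis (posterior part),ILPOp,2.15,65.4,74.9,1.3,1.3,0,9.814
Ambiens,AMB,0.3,21.5,23.1,24.6,28.6,0,3.952
Femorotibialis lateralis,FMTL,1.565,28,37.1,0.6,0.6,21,14.913
Femorotibialis intermedius,FMTI,0.449,13.6,14.7,25.4,32.5,22.5,9.33
Femorotibialis medialis,FMTM,2.09,31.4,31,16,15.5,35.3,18.845
Iliofibularis,ILFB,2.133,70,71,0.7,0.7,0,8.263
Flexor cruris lateralis pars pelvica,FCLP,4.52,63.6,77.4,4.1,4.2,0,20.101
Flexor cruris lateralis pars accessoria,FCLA,0.844,32.8,39.9,23.8,30.4,0,7.276
Flexor cruris medialis,FCM,0.247,36.7,41.3,15.3,16.8,0,1.907
Iliofemoralis externus,IFE,0.212,9.8,11.3,5.3,6,0,6.098
Iliotrochantericus cranialis,ITCr,0.325,14.4,15.8,11.4,13.1,7.8,6.378
Iliotrochantericus medius,ITM,0.066,10,12.9,2.9,3.3,10.4,1.86
Iliotrochantericus caudalis (anterior part),ITCaa,1.35,15.5,19.1,12.1,16.1,26.2,24.65
Iliotrochantericus caudalis (posterior part),ITCap,1.35,15.5,23.2,1,1.1,26.2,24.65
Ischiofemoralis,ISF,0.56,14.3,15.5,13.8,15.8,24.8,11.114
Obturatorius medialis,OM,0.619,12,13.6,20.2,22.4,30,14.655
Obturatorius lateralis,OL,0.0320,14.7,14.7,0.2,0.2,0,0.624
Caudofemoralis pars pelvica,CFP,1.009,26.7,32.8,0.2,0.2,0,10.687
Puboischiofemoralis medialis et lateralis,PIFML,1.543,36,38.5,0.3,0.3,0,12.134
Gastrocnemius pars lateralis,GL,2.55,24.2,26.6,59.2,68.3,30,29.816
Gastrocnemius pars intermedia,GI,0.438,36.2,39.3,44,53.5,15,3.425
Gastrocnemius pars medialis,GM,2.251,25.2,27.4,50.2,64.2,20.8,25.305
Fibularis longus,FL,2.315,27.1,28.2,105.6,118.4,25.4,24.198
Tibialis cranialis capute femorale,TCf,0.519,15.6,17,62.4,67.3,24.8,9.415
Tibialis cranialis caput tibiale,TCt,0.979,30.6,37.3,31.3,38.9,18.5,9.049
Extensor digitorum longus,EDL,0.295,17.8,17.9,109.7,112.6,5,4.688
Flexor digitorum longus,FDL,0.563,26.7,27.4,89,104.7,25.6,5.963
Flexor hallucis longus,FHL,0.304,16.8,16.9,135.6,143.7,27,5.124
Flexor perforatus digitorum II,FP2,0.524,20.4,20.6,116.6,124.4,22.4,7.277
Flexor perforans et perforatus digitorum II,FPP2,0.369,19.4,19.6,119.3,130.6,30,5.378
Flexor perforatus digitorum III,FP3,0.264,16.2,16.3,128.2,139,30,4.615
Flexor perforans et perforatus digitorum III,FPP3,0.214,17,17.1,135.3,140.8,22,3.569
Flexor perforatus digitorum IV,FP4,0.263,19.2,19.4,115.6,125.4,25,3.879
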