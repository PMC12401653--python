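analyte,weighting,cal1,cal2,cal3,cal4,cal5,lloq,uloq,qc_low,qc_high,one_point_conc,therapeutic_low,therapeutic_high,toxic_above,range_is_sum,sum_group,dual_status,working_solution,rt_min
Alprazolam,1/x^2,50,125,250,375,500,50,500,60,400,250,5,50,100,false,,false,,
Amisulpride,1/x^2,100,500,1000,1500,2000,100,2000,120,1600,1000,100,400,640,false,,false,,
Amitriptyline,1/x^2,100,500,1000,1500,2000,100,2000,120,1600,1000,50,300,500,false,,false,,
Aripiprazole,Equal,250,500,1000,1500,2000,250,2000,300,1600,1000,100,350,1000,false,,false,,
Biperiden,1/x^2,50,125,250,375,500,50,500,60,400,250,1.0,6.5,13,false,,false,,
Bisoprolol,Equal,100,500,1000,1500,2000,100,2000,120,1600,1000,10,100,200,false,,false,,
Bromazepam,Equal,1000,1500,2000,2500,3000,1000,3000,1200,2400,2000,50,200,300,false,,false,,
Carbamazepine,1/x^2,2500,5000,10000,15000,20000,2500,20000,3000,16000,10000,2000,12000,10000,false,,false,,
Chlorprothixene,Equal,250,500,1000,1500,2000,250,2000,300,1600,1000,20,300,400,false,,false,,
Citalopram,1/x^2,100,500,1000,1500,2000,100,2000,120,1600,1000,50,110,220,false,,false,,
Clobazam,1/x^2,100,500,1000,1500,2000,100,2000,120,1600,1000,30,300,500,false,,false,,
Clozapine,1/x^2,100,500,1000,1500,2000,100,2000,120,1600,1000,100,600,600,false,,false,,
Codeine,1/x^2,250,500,1000,1500,2000,250,2000,300,1600,1000,30,250,500,false,,false,,
Desipramine,Equal,250,500,1000,1500,2000,250,2000,300,1600,1000,10,500,500,false,,false,,
Diazepam,1/x^2,500,1000,1500,2000,2500,500,2500,600,2000,1500,100,2500,5000,true,diazepam,false,,
Diazepam-M (nor-)/Nordiazepam,Equal,750,1000,1500,2000,2500,750,2500,900,2000,1500,120,800,1500,false,diazepam,true,,
Dihydrocodeine,1/x^2,250,500,1000,1500,2000,250,2000,300,1600,1000,30,250,500,false,,false,,
Diltiazem,1/x^2,100,500,1000,1500,2000,100,2000,120,1600,1000,30,250,800,false,,false,,
Diphenhydramine,1/x^2,500,1000,1500,2000,2500,500,2500,600,2000,1500,50,100,1000,false,,false,,
Doxepin,1/x^2,100,500,1000,1500,2000,100,2000,120,1600,1000,50,150,300,true,doxepin,false,,
Doxepin-M (nor-),Equal,50,125,250,375,500,50,500,60,400,250,,,,false,doxepin,false,,
Doxylamine,1/x^2,200,500,1000,1500,2000,200,2000,250,1600,1000,50,200,1000,false,,false,,
Flupirtine,Equal,1000,1500,2000,2500,3000,1000,3000,1200,2400,2000,500,1500,3000,false,,false,,
Haloperidol,1/x^2,50,125,250,375,500,50,500,60,400,250,1,17,50,false,,false,,
Hydromorphone,1/x^2,50,125,250,375,500,50,500,60,400,250,5,30,100,false,,false,,
Imipramine,1/x^2,250,500,1000,1500,2000,250,2000,300,1600,1000,50,350,500,false,,false,,
Ketamine,1/x^2,1000,2500,5000,7500,10000,1000,10000,1200,8000,5000,100,6000,7000,false,,false,,
Levomepromazine,1/x^2,200,500,1000,1500,2000,200,2000,250,1600,1000,5,200,400,false,,false,,
Lorazepam,1/x^2,500,1000,1500,2000,2500,500,2500,600,2000,1500,20,250,300,false,,false,,
Maprotiline,1/x^2,100,500,1000,1500,2000,100,2000,120,1600,1000,75,130,500,false,,false,,
Melperone,1/x^2,100,500,1000,1500,2000,100,2000,120,1600,1000,30,100,200,false,,false,,
Methadone,1/x^2,100,500,1000,1500,2000,100,2000,120,1600,1000,50,600,600,false,,false,,
Metoclopramide,1/x^2,100,500,1000,1500,2000,100,2000,120,1600,1000,10,150,200,false,,false,,
Metoprolol,1/x^2,100,500,1000,1500,2000,100,2000,120,1600,1000,20,600,7800,false,,false,,
Mianserin,1/x^2,50,125,250,375,500,50,500,60,400,250,15,70,250,false,,false,,
Midazolam,1/x^2,100,500,1000,1500,2000,100,2000,120,1600,1000,40,250,1000,false,,false,,
Mirtazapine,1/x^2,150,500,1000,1500,2000,150,2000,180,1600,1000,30,300,1000,false,,false,,
Moclobemide,Equal,500,1500,2500,4000,5000,500,5000,600,4000,2500,300,3000,2000,false,,false,,
Olanzapine,1/x^2,50,125,250,375,500,50,500,60,400,250,1,80,100,false,,false,,
Opipramol,1/x^2,100,500,1000,1500,2000,100,2000,120,1600,1000,50,500,1000,false,,false,,
Oxazepam,Equal,1000,1500,2000,2500,3000,1000,3000,1200,2400,2000,200,1500,2000,false,,false,,
Oxcarbazepine,1/x^2,2500,10000,20000,40000,80000,2500,80000,3000,65000,20000,10000,35000,35000,false,,false,,
Oxycodone,1/x^2,250,500,1000,1500,2000,250,2000,300,1600,1000,5,100,200,false,,false,,
Paracetamol,1/x^2,2500,30000,60000,90000,120000,2500,120000,3000,96000,60000,5000,25000,100000,false,,false,,
Paroxetine,1/x^2,50,125,250,375,500,50,500,60,400,250,2,65,400,false,,false,,
Perazine,1/x^2,100,500,1000,1500,2000,100,2000,120,1600,1000,10,230,460,false,,false,,
Pethidine,1/x^2,500,1000,1500,2000,2500,500,2500,600,2000,1500,100,800,1000,false,,false,,
Pethidine-M (nor-),Equal,50,125,250,375,500,50,500,60,400,250,,,,false,,false,,
Pipamperone,Equal,250,500,1000,1500,2000,250,2000,300,1600,1000,100,400,500,false,,false,,
Promethazine,1/x^2,100,500,1000,1500,2000,100,2000,120,1600,1000,10,200,1000,false,,false,,
Prothipendyl,Equal,50,125,250,375,500,50,500,60,400,250,30,80,500,false,,false,,
Quetiapine,1/x^2,100,500,1000,1500,2000,100,2000,120,1600,1000,100,500,1800,false,,false,,
Ramipril,1/x^2,50,125,250,375,500,50,500,60,400,250,1,40,80,false,,false,,
Risperidone,1/x^2,50,125,250,375,500,50,500,60,400,250,20,60,120,true,risperidone,false,,
Risperidone-M (9-hydroxy-)/Paliperidone,1/x^2,100,500,1000,1500,2000,100,2000,120,1600,1000,20,60,120,false,risperidone,true,,
Sertraline,Equal,250,500,1000,1500,2000,250,2000,300,1600,1000,10,500,300,false,,false,,
Sulpiride,Equal,500,1000,1500,2000,2500,500,2500,600,2000,1500,50,1000,1500,false,,false,,
Tapentadol,1/x^2,100,500,1000,1500,2000,100,2000,120,1600,1000,10,300,,false,,false,,
Temazepam,1/x^2,500,1000,1500,2000,2500,500,2500,600,1600,1500,20,900,1000,false,,false,,
Tilidine,1/x^2,100,500,1000,1500,2000,100,2000,300,1600,1000,50,300,,false,,false,,
Tilidine-M (nor-),1/x^2,100,500,1000,1500,2000,100,2000,120,1600,1000,,,,false,,false,,
Tramadol,1/x^2,250,500,1000,1500,2000,250,2000,300,1600,1000,100,1000,1000,false,,false,,
Tramadol-M (O-demethyl),1/x^2,100,500,1000,1500,2000,100,2000,120,1600,1000,,,,false,,false,,
Venlafaxine,1/x^2,100,500,1000,1500,2000,100,2000,120,1600,1000,100,400,1000,true,venlafaxine,false,,
Venlafaxine-M (O-demethyl),1/x^2,100,500,1000,1500,2000,100,2000,120,1600,1000,,,,false,venlafaxine,false,,
Verapamil,Equal,100,500,1000,1500,2000,100,2000,120,1600,1000,10,400,1000,false,,false,,
Zolpidem,1/x^2,100,500,1000,1500,2000,100,2000,120,1600,1000,80,200,500,false,,false,,
Zopiclone,Equal,100,500,1000,1500,2000,100,2000,120,1600,1000,10,120,150,false,,false,,
Zuclopenthixol,1/x^2,50,125,250,375,500,50,500,60,400,250,4,100,100,false,,false,,
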