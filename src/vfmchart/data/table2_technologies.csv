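id,name,indication,n_patients,Lives saved,Life-prolongation benefits,Quality-of-life (QoL) gains,If this technology were not to be funded,Other important social or ethical benefits,total_cost,evidence,x_factors
t1,Smoking cessation drugs,smokers,6000,"Very many: >500 lives saved",Large benefits,Large QoL gains,Many/most patients will be able to pay for it themselves (privately),Yes,5.29,high,not smoking is a personal choice
t2,Taxotere,head and neck cancer,200,None (or not yet known),Large benefits,None/very small (or not yet known),Many/most patients will not receive any treatment for condition,Yes,4.6,high,none
t3,Herceptin,breast cancer - adjuvant treatment,700,"Few: 1-50 lives saved",Medium benefits,Small QoL gains,Many/most patients will get an alternative treatment (less effective) already funded by government,Yes,124,high,none
t4,Elaprase,Hunter syndrome,3,"Few: 1-50 lives saved",None/very small (or not yet known),Medium QoL gains,Many/most patients will not receive any treatment for condition,Yes,5.45,poor,orphan drug
t5,Visudyne,age-related macular degeneration,1050,None (or not yet known),None/very small (or not yet known),Large QoL gains,Many/most patients will not receive any treatment for condition,Yes,26.47,high,none
t6,Left-ventricular assist devices,terminal heart failure,12,"Few: 1-50 lives saved",Small benefits,Small QoL gains,Many/most patients will not receive any treatment for condition,Yes,4.83,high,none
t7,Statins,hypercholesterolemia,5600,None (or not yet known),Medium benefits,Medium QoL gains,Many/most patients will be able to pay for it themselves (privately),Yes,16,high,strategic considerations
t8,Pain relief,neuropathic pain,14250,None (or not yet known),None/very small (or not yet known),Large QoL gains,Many/most patients will get an alternative treatment (less effective) already funded by government,Yes,46,high,none
t9,Revlimid,multiple myeloma - 3rd-line treatment,200,None (or not yet known),Medium benefits,None/very small (or not yet known),Many/most patients will not receive any treatment for condition,Yes,39,medium,none
t10,Dental care,children,20000,None (or not yet known),None/very small (or not yet known),Medium QoL gains,Many/most patients will not receive any treatment for condition,Yes,65,high,political considerations
t11,Growth hormone,short-statured children,3900,None (or not yet known),None/very small (or not yet known),Medium QoL gains,Many/most patients will not receive any treatment for condition,Yes,25.6,high,none
t12,Avastin [Bevacizumab],colon cancer,700,None (or not yet known),Medium benefits,Small QoL gains,Many/most patients will not receive any treatment for condition,None/Very small (or not yet known),76.27,medium,none
t13,Over-active bladder drugs,"urinary urge, incontinence",21000,None (or not yet known),None/very small (or not yet known),Large QoL gains,Many/most patients will be able to pay for it themselves (privately),Yes,37,high,none
t14,Fuzeon,HIV,45,None (or not yet known),Medium benefits,Small QoL gains,Many/most patients will get an alternative treatment (less effective) already funded by government,None/Very small (or not yet known),3.33,high,none
t15,Long-acting insulins,diabetes,10000,None (or not yet known),Small benefits,Medium QoL gains,Many/most patients will get an alternative treatment (less effective) already funded by government,None/Very small (or not yet known),17.83,high,none
t16,Contraceptives,adolescent girls,20000,None (or not yet known),None/very small (or not yet known),Medium QoL gains,Many/most patients will be able to pay for it themselves (privately),Yes,3.11,high,"socio-ethical, religious considerations"
t17,Erbitux,colon cancer - for KRAS mutation negative,210,None (or not yet known),Small benefits,Small QoL gains,Many/most patients will get an alternative treatment (less effective) already funded by government,None/Very small (or not yet known),47.26,medium,none
t18,Humira,psoriatic arthritis,60,None (or not yet known),None/very small (or not yet known),Small QoL gains,Many/most patients will get an alternative treatment (less effective) already funded by government,None/Very small (or not yet known),3.49,medium,none
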