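acoh_equiv,naoh_equiv,menhnh2_equiv,dsi2,ptc,ms,temp_c,vol_ml_per_g,solvent,n2_pct,n1_pct,conv_pct,round_label,strategy
5,0,5,1,1,1,50,30,p-Cymene,70,30,98,BO1,GPR_ucb_2_n2
0,5,2,1,0,1,50,30,2-MeTHF,8,92,59,BO1,RFR_ucb_2_n2
3,0,5,1,1,1,50,10,MeCN,65,35,98,BO2,MLP_ei_05_n1
0,5,5,0,0,1,25,10,diethylamine,2,98,63,BO2,RFR_ucb_2_n2
5,0,5,0,0,0,0,10,isoamyl alcohol,66,34,98,BO3,MLP_ucb_2_n1
0,2.8,5,0,1,0,25,10,MTBE,2,98,80,BO3,RFR_ei_05_n1
5,0,3,0,1,0,25,10,cyclohexane,71,29,97,BO4,GPR_ei_05_n1
0,2.8,5,0,1,0,12.5,10,tributylamine,1,99,76,BO4,RFR_ucb_2_n2
5,0,5,1,1,0,12.5,10,m-cresol,78,22,97,BO5,MLP_ucb_2_n1
0,1.7,5,0,0,0,25,10,triethylamine,5,95,48,BO5,GPR_ucb_2_n2
0,0.6,5,0,1,0,12.5,10,MTBE,84,16,61,BO6,RFR_ei_05_n1
0,5,5,1,1,1,12.5,23,oleyl alcohol,1,99,85,BO6,Grad_ei_05_n2
0.6,0,5,0,0,0,0,10,MTBE,72,28,78,BO7,RFR_ei_05_n1
0,5,5,1,0,1,12.5,30,tributylamine,1,99,85,BO7,Grad_ei_05_n2
5,0,5,1,1,0,12.5,8,m-cresol,78,22,100,BO8,RFR_ucb_2_n1
0,5,4,1,0,1,12.5,30,oleyl alcohol,1,99,81,BO8,Grad_ucb_2_n2
0.6,0,16,0,0,0,0,23,n-propylamine,97,3,69,BO9,GPR_ei_05_n1
0,5,20,1,0,0,50,30,tributylamine,8,92,96,BO9,MLP_ucb_2_n2
0.6,0,20,0,1,0,0,10,pyrrolidine,93,7,88,B10,GPR_ei_05_n1
0,5,13,1,0,0,0,10,tributylamine,1,99,95,B10,MLP_ei_05_n2
0,0.5,14,1,0,0,0,10,tributylamine,90,10,99,P1,N2_pred_best
0,5,20,0,0,0,12.5,30,MTBE,1,99,86,P1,N1_pred_best
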