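casrn,name,n_active,min_lel,n_inactive,max_hdt,design_differs,active_designs,inactive_designs
80-05-7,Bisphenol A,37,2,6,1000,false,,
446-72-0,Genistein,27,1,1,5,false,,
72-43-5,Methoxychlor,18,20,1,200,false,,
789-02-6,"o,p'-DDT",15,1,1,100,false,,
94-26-8,Butylparaben,8,50,2,1000,true,Imm_Rat_Inj:5;OVX_Mouse_Inj:2;OVX_Rat_Inj:1,Imm_Rat_Oral:1;OVX_Mouse_Oral:1
56-53-1,Diethylstilbestrol,8,0.00005,1,0.00005,false,,
104-40-5,"4-n-Nonylphenol (linear, para)",5,75,4,200,false,,
140-66-9,4-tert-Octylphenol,3,56,1,250,true,,
120-47-8,Ethylparaben,1,180,3,1000,false,,
119-61-9,Benzophenone,1,500,2,200,false,,
99-76-3,Methylparaben,1,55,2,800,true,,
56-55-3,Benz[a]anthracene,1,1,2,300,true,,
1806-26-4,4-Octylphenol,1,100,2,200,true,,
94-13-3,Propylparaben,1,65,2,1000,true,,
52645-53-1,Permethrin,1,800,1,150,true,,
50-55-5,Reserpine,1,3,1,3,true,,
520-36-5,Apigenin,1,5,1,200,true,,
486-66-8,Daidzein,1,600,1,200,true,,
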