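casrn,name,n_active,n_inactive,bioactivity,min_lel,max_hdt,lel_unit
50-28-2,Estradiol,25,0,active,0.00001,,mg/kg/day
57-63-6,Ethinyl Estradiol,59,0,active,0.0001,,mg/kg/day
72-33-3,Mestranol,3,0,active,0.00008,,mg/rat/day
50-27-1,Estriol,4,0,active,0.002,,mg/rat/day
10540-29-1,Tamoxifen,12,0,active,0.01,,mg/kg/day
57-91-0,Alfatradiol,2,0,active,0.4,,mg/kg/day
68-22-4,Norethindrone,2,0,active,2,,mg/kg/day
53-16-7,Estrone,9,0,active,2,,mg/kg/day
474-86-2,Equilin,2,0,active,2,,mg/kg/day
17924-92-4,Zearalenone,4,0,active,2,,mg/kg/day
50-41-9,Clomiphene citrate,2,0,active,2,,mg/kg/day
1478-61-1,Bisphenol AF,4,0,active,4,,mg/kg/day
58-18-4,Methyltestosterone,3,0,active,10,,mg/kg/day
80-09-1,Bisphenol S,2,0,active,20,,mg/kg/day
77-40-7,Bisphenol B,2,0,active,20,,mg/kg/day
599-64-4,4-Cumylphenol,2,0,active,20,,mg/kg/day
521-18-6,Dihydrotestosterone,3,0,active,20,,mg/kg/day
104-43-8,4-Dodecylphenol,3,0,active,40,,mg/kg/day
98-54-4,4-tert-Butylphenol,2,0,active,100,,mg/kg/day
131-56-6,"2,4-Dihydroxybenzophenone",3,0,active,100,,mg/kg/day
80-46-6,4-tert-Amylphenol,4,0,active,200,,mg/kg/day
5153-25-3,2-Ethylhexyl 4-hydroxybenzoate,2,0,active,200,,mg/kg/day
131-55-5,Benzophenone-2,6,0,active,200,,mg/kg/day
556-67-2,Octamethylcyclotetrasiloxane,3,0,active,250,,mg/kg/day
51630-58-1,Fenvalerate,0,2,inactive,,80,mg/kg/day
1461-22-9,Tributyltin chloride,0,2,inactive,,200,mg/kg/day
99-96-7,4-Hydroxybenzoic acid,0,2,inactive,,1000,mg/kg/day
87-86-5,Pentachlorophenol,0,2,inactive,,1000,mg/kg/day
84-75-3,Dihexyl phthalate,0,2,inactive,,1000,mg/kg/day
84-74-2,Dibutyl phthalate,0,2,inactive,,1000,mg/kg/day
84-61-7,Dicyclohexyl phthalate,0,2,inactive,,1000,mg/kg/day
61-82-5,Amitrole,0,2,inactive,,1000,mg/kg/day
520-18-3,Kaempferol,0,3,inactive,,1000,mg/kg/day
117-81-7,Bis(2-ethylhexyl) phthalate,0,2,inactive,,1000,mg/kg/day
103-23-1,Bis(2-ethylhexyl) hexanedioate,0,2,inactive,,1000,mg/kg/day
84-66-2,Diethyl phthalate,0,2,inactive,,2000,mg/kg/day
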