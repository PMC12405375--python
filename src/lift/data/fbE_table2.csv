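location,generation,crosses,pollinated_flowers,fruits,seeds,sown,scab_eliminated,pre_mas_losses,mas_tested,rgene_carriers,selected_for_lift,parents_next_gen
field,F1,2,1288,227,977,977,3,395,579,279,57,16
field,pBC1,7,992,77,279,279,0,31,248,92,81,6
field,pBC2,5,1329,98,574,518,72,272,174,105,21,9
field,pBC3,2,134,21,119,119,10,92,17,6,0,0
field,pBC4,4,1068,231,1284,731,115,242,374,167,75,2
field,pBC5,0,0,0,0,0,0,0,0,0,0,0
LIFT,F1,0,0,0,0,0,0,0,0,0,0,0
LIFT,pBC1,13,328,119,507,287,0,125,162,49,40,2
LIFT,pBC2,14,247,41,218,157,0,84,73,39,30,11
LIFT,pBC3,34,457,88,572,572,0,220,352,181,129,13
LIFT,pBC4,32,707,64,472,472,11,97,364,194,92,0
LIFT,pBC5,3,74,7,31,31,0,4,27,14,10,0
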