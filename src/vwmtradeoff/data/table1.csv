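study,experiment,n,task,stimulus,set_sizes,duration_ms,observed_tradeoff,can_predict
Zhang & Luck,Experiment 1a,13,recall,colour,4,200,no,yes
Zhang & Luck,Experiment 1b,13,recall,colour,4,200,no,yes
Zhang & Luck,Experiment 2,14,recall,colour,4,200,no,yes
Zhang & Luck,Experiment 3,10,recall,colour,4,200,no,yes
Zhang & Luck,Experiment 4,10,recall,colour,6,200,no,yes
Gao et al.,Experiment 1,19,change detection (CDA),orientation,2;4,500,yes,yes
Murray et al.,Experiment 1,12,change detection,orientation,4,200,no,yes
Murray et al.,Experiment 2,20,change detection,orientation,4,200,no,yes
Murray et al.,Experiment 3,20,change detection,orientation,4,200,no,yes
Murray et al.,Experiment 4,20,change detection,orientation,4,200,no,yes
Machizawa et al.,Experiment 1,20,change detection,orientation,2;4,200,yes;no,yes
Machizawa et al.,Experiment 2,20,change detection (CDA),orientation,2;4,200,yes;no,yes
Ye et al. (2017 CDA),Experiment 1,14,change detection (CDA),colour,2;3;4,100,no,yes
He et al.,Experiment 1,12,change detection (CDA),colour,2;4,200,no,yes
He et al.,Experiment 2,21,change detection (CDA),colour,2;4,200,no,yes
Fougnie et al.,Experiment 1,18,recall,colour,5,1200,yes,yes
Fougnie et al.,Supplementary experiment,18,recall,colour,5,200,yes,no
Fougnie et al.,Experiment 2,18,recall,colour,5,1200,yes,yes
Bocincova et al.,Experiment 1,60,recall,colour,2;4,150,no,yes
Ye et al. (2017),Experiment 1,47,recall,orientation,4,200,no,yes
Ye et al. (2017),Experiment 2,50,recall,orientation,2,200,yes,yes
Ye et al. (2017),Experiment 3,47,recall,orientation,4,500,yes,yes
Ramaty & Luria,Experiment 1,20,recall,colour,5,1200,yes,yes
Ramaty & Luria,Experiment 2,20,recall,colour,5,300,no,yes
Ramaty & Luria,Experiment 3,20,recall,colour,5,1200,no,no
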