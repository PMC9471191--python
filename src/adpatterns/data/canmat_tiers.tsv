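drug_id	role	line	superior_efficacy
agomelatine	monotherapy	1	0
bupropion	monotherapy	1	0
citalopram	monotherapy	1	0
desvenlafaxine	monotherapy	1	0
duloxetine	monotherapy	1	0
escitalopram	monotherapy	1	1
fluoxetine	monotherapy	1	0
fluvoxamine	monotherapy	1	0
mianserin	monotherapy	1	0
milnacipran	monotherapy	1	0
mirtazapine	monotherapy	1	1
paroxetine	monotherapy	1	0
sertraline	monotherapy	1	1
venlafaxine	monotherapy	1	1
vortioxetine	monotherapy	1	0
amitriptyline	monotherapy	2	0
clomipramine	monotherapy	2	0
imipramine	monotherapy	2	0
doxepin	monotherapy	2	0
trazodone	monotherapy	2	0
moclobemide	monotherapy	2	0
reboxetine	monotherapy	3	0
aripiprazole	adjunct	1	0
quetiapine	adjunct	1	0
risperidone	adjunct	1	0
brexpiprazole	adjunct	2	0
bupropion	adjunct	2	0
lithium	adjunct	2	0
mirtazapine	adjunct	2	0
modafinil	adjunct	2	0
olanzapine	adjunct	2	0
triiodothyronine	adjunct	2	0
trazodone	adjunct	3	0
ziprasidone	adjunct	3	0
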