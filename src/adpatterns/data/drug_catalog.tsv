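drug_id	ad_class	is_antidepressant
citalopram	SSRI	1
escitalopram	SSRI	1
fluoxetine	SSRI	1
fluvoxamine	SSRI	1
paroxetine	SSRI	1
sertraline	SSRI	1
venlafaxine	SNRI	1
desvenlafaxine	SNRI	1
duloxetine	SNRI	1
milnacipran	SNRI	1
amitriptyline	TCA	1
clomipramine	TCA	1
imipramine	TCA	1
doxepin	TCA	1
mirtazapine	NaSSA	1
mianserin	NaSSA	1
agomelatine	other_AD	1
trazodone	other_AD	1
bupropion	other_AD	1
reboxetine	other_AD	1
maprotiline	other_AD	1
vortioxetine	other_AD	1
moclobemide	other_AD	1
quetiapine	antipsychotic	0
aripiprazole	antipsychotic	0
risperidone	antipsychotic	0
olanzapine	antipsychotic	0
brexpiprazole	antipsychotic	0
ziprasidone	antipsychotic	0
lithium	mood_stabilizer	0
valproate	mood_stabilizer	0
buspirone	other_adjunct	0
modafinil	other_adjunct	0
triiodothyronine	other_adjunct	0
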