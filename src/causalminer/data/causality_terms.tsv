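canonical	strength	direction	variants
activate	1.00	forward	activate|activates|activated|activating
activated by	0.75	reverse	activated by
actuate	1.00	forward	actuate|actuates|actuated|actuating
actuated by	1.00	reverse	actuated by
affect	1.00	forward	affect|affects|affected|affecting
affected by	0.75	reverse	affected by
arisen from	0.75	reverse	arisen from
arising from	0.75	reverse	arising from
arouse	0.75	forward	arouse|arouses|aroused|arousing
associate with	0.25	forward	associate with|associates with|associated with|associating with
attributable to	0.75	reverse	attributable to
attributed to	0.75	reverse	attributed to
because of	1.00	reverse	because of
began by	0.75	reverse	began by
begin	0.75	forward	begin|begins|began|begun|beginning
bring	0.75	forward	bring|brings|brought|bringing
brought by	0.75	reverse	brought by
call	0.75	forward	call|calls|called|calling
called out by	0.75	reverse	called out by
cause	1.00	forward	cause|causes|caused|causing
caused by	1.00	reverse	caused by
commence	0.50	forward	commence|commences|commenced|commencing
commenced by	0.50	reverse	commenced by
complicate	0.50	forward	complicate|complicates|complicated|complicating
complicated by	0.50	reverse	complicated by
complication	0.50	forward	complication|complications
contribute	0.75	forward	contribute|contributes|contributed|contributing
contributed by	0.50	reverse	contributed by
create	1.00	forward	create|creates|created|creating
created by	1.00	reverse	created by
develop	1.00	forward	develop|develops|developed|developing
developed by	1.00	reverse	developed by
due to	1.00	reverse	due to
educe	0.75	forward	educe|educes|educed|educing
educed by	0.75	reverse	educed by
effectuate	1.00	forward	effectuate|effectuates|effectuated|effectuating|effect|effects|effected|effecting
effectuated by	1.00	reverse	effectuated by
elevate	0.75	forward	elevate|elevates|elevated|elevating
elevated by	0.75	reverse	elevated by
elicit	0.75	forward	elicit|elicits|elicited|eliciting
elicited by	0.75	reverse	elicited by
enhance	0.75	forward	enhance|enhances|enhanced|enhancing
enhanced by	0.75	reverse	enhanced by
entail	0.50	forward	entail|entails|entailed|entailing
entailed by	0.75	reverse	entailed by
fire up	1.00	forward	fire up|fires up|fired up|firing up
fired by	1.00	reverse	fired by
generate	1.00	forward	generate|generates|generated|generating
generated by	1.00	reverse	generated by
give birth to	1.00	forward	give birth to|gives birth to|gave birth to|given birth to|giving birth to
give rise to	1.00	forward	give rise to|gives rise to|gave rise to|given rise to|giving rise to
hasten	0.50	forward	hasten|hastens|hastened|hastening
hastened by	0.50	reverse	hastened by
implied by	0.50	reverse	implied by
imply	0.50	forward	imply|implys|implyed|implying
incite	0.75	forward	incite|incites|incited|inciting
incited by	0.75	reverse	incited by
induce	0.75	forward	induce|induces|induced|inducing
induced by	0.75	reverse	induced by
infect	0.75	forward	infect|infects|infected|infecting
infected by	1.00	reverse	infected by
influence	0.75	forward	influence|influences|influenced|influencing
influenced by	0.75	reverse	influenced by
initiate	1.00	forward	initiate|initiates|initiated|initiating
initiated by	1.00	reverse	initiated by
interact	0.25	forward	interact|interacts|interacted|interacting
kick up	0.75	forward	kick up|kicks up|kicked up|kicking up
kicked up by	0.75	reverse	kicked up by
kindle	0.75	forward	kindle|kindles|kindled|kindling
kindled by	0.75	reverse	kindled by
launch	0.75	forward	launch|launchs|launched|launching
launched by	0.75	reverse	launched by
lead	0.75	forward	lead|leads|led|leading|lead to|leads to|led to|leading to
led by	0.75	reverse	led by
link	0.25	forward	link|links|linked|linking
made by	1.00	reverse	made by
make	1.00	forward	make|makes|made|making
originate	0.75	forward	originate|originates|originated|originating
originated by	0.75	reverse	originated by
owe	0.75	forward	owe|owes|owed|owing
produce	1.00	forward	produce|produces|produced|producing
produced by	1.00	reverse	produced by
promote	0.75	forward	promote|promotes|promoted|promoting
promoted by	0.75	reverse	promoted by
provoke	0.75	forward	provoke|provokes|provoked|provoking
provoked by	0.75	reverse	provoked by
relate	0.25	forward	relate|relates|related|relating
result	1.00	forward	result|results|resulted|resulting
resulting from	1.00	reverse	resulting from
rise	1.00	forward	rise|rises|rose|risen|rising
secondary to	0.50	reverse	secondary to
set off	0.75	forward	set off|sets off|setting off
spark	1.00	forward	spark|sparks|sparked|sparking
sparked by	1.00	reverse	sparked by
start	1.00	forward	start|starts|started|starting
started by	1.00	reverse	started by
stem from	1.00	reverse	stem from|stems from|stemmed from|stemming from
stimulate	0.75	forward	stimulate|stimulates|stimulated|stimulating
stimulated by	0.75	reverse	stimulated by
stir	0.75	forward	stir|stirs|stirred|stirring
stirred by	0.75	reverse	stirred by
trigger	1.00	forward	trigger|triggers|triggered|triggering
triggered by	1.00	reverse	triggered by
unleash	1.00	forward	unleash|unleashs|unleashed|unleashing
unleashed by	1.00	reverse	unleashed by
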