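# Sentence templates for the synthetic forum generator.
# Format: class(es) TAB template. A template for a mention class contains
# exactly one {TREATMENT} slot. Lines with several comma-separated classes
# are ambiguous: their wording underdetermines the attribution, and the
# generator assigns them to any class in the list. "none" lines are filler
# sentences without any treatment mention (and must not contain gazetteer
# terms).
pt	My son is now on {TREATMENT} and doing well.
pt	We started {TREATMENT} last month.
pt	My daughter has been taking {TREATMENT} for six weeks.
pt	We finally began {TREATMENT} after the diagnosis.
pt	He started {TREATMENT} again yesterday.
pt	She has been using {TREATMENT} since spring.
pt-gen	The doctor suggested {TREATMENT} for my son.
pt-gen	The pediatrician recommended {TREATMENT} for him.
pt-gen	We are considering {TREATMENT} for our daughter.
pt-gen	The doctor wants him to try {TREATMENT} soon.
pt-gen	Our doctor mentioned {TREATMENT} at the last visit.
cg	I take {TREATMENT} myself every night.
cg	I use {TREATMENT} myself to cope with the stress.
cg	I rely upon {TREATMENT} when i get migraines.
cg	I personally prefer {TREATMENT} for my own headaches.
others	Her daughter tried {TREATMENT} last year.
others	Another mom said her son uses {TREATMENT} daily.
others	My neighbor gives her child {TREATMENT} every morning.
others	A friend of ours says her kid improved with {TREATMENT} quickly.
gen	{TREATMENT} has no scientific evidence behind it.
gen	There are many studies about {TREATMENT} online.
gen	Has anyone read anything regarding {TREATMENT} recently?
gen	People keep debating whether {TREATMENT} actually works.
pt,pt-gen	We discussed {TREATMENT} for my son at the clinic.
pt,gen	We looked into {TREATMENT} for a while.
pt-gen,gen	Someone brought up {TREATMENT} in the thread.
cg,others	In our house {TREATMENT} gets mentioned a lot.
others,gen	People around here love {TREATMENT} apparently.
none	How was your weekend everyone?
none	Thanks so much for all the support here.
none	We had a rough night again.
none	The school meeting went better than expected.
none	Hang in there, it does get easier.
none	Our insurance denied the claim again this week.
none	He slept through the night for once!
none	Does anyone else deal with picky eating?
none	I am so tired today.
none	Welcome to the forum, glad you found us.
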