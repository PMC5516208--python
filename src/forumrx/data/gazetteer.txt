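# ASD-treatment gazetteer: one lowercase term per line, "#" comments.
# Compiled from treatments commonly discussed in autism parent forums
# (conventional drugs, supplements, diets, behavioural and alternative
# therapies), including spelling/inflection variants listed separately.
chelation
chelating
chelator
chelation therapy
probiotics
probiotic
zinc
enzymes
enzyme
digestive enzymes
melatonin
special education
antibiotics
antibiotic
speech therapy
early intervention
magnesium
calcium
nystatin
activated charcoal
charcoal
progesterone
cod liver oil
molybdenum glycinate chelate
sensory integration
sensory integration therapy
aloe vera
pyridoxine hydrochloride
risperdal
risperidone
homeopathy
homeopathic remedies
vitamin
vitamins
thimerosal
vitamin a
vitamin b6
vitamin b12
methyl b12
b12 shots
vitamin c
vitamin d
vitamin e
multivitamin
folic acid
folinic acid
omega 3
fish oil
flax seed oil
epsom salt baths
epsom salts
glutathione
dmg
tmg
dmsa
edta
secretin
gfcf diet
gluten free diet
casein free diet
gluten free casein free diet
scd diet
specific carbohydrate diet
feingold diet
ketogenic diet
aba
aba therapy
applied behavior analysis
floortime
rdi
son-rise program
pecs
picture exchange
occupational therapy
physical therapy
play therapy
music therapy
art therapy
hippotherapy
therapeutic riding
auditory integration training
vision therapy
social skills training
social skills group
speech and language therapy
oral motor therapy
craniosacral therapy
chiropractic
acupuncture
hyperbaric oxygen therapy
hbot
oxytocin
naltrexone
low dose naltrexone
abilify
aripiprazole
prozac
fluoxetine
zoloft
sertraline
paxil
celexa
lexapro
ritalin
methylphenidate
concerta
adderall
strattera
clonidine
tenex
guanfacine
depakote
valproic acid
lamictal
topamax
tegretol
trileptal
keppra
seroquel
zyprexa
geodon
haldol
buspar
ativan
klonopin
xanax
benadryl
claritin
zyrtec
singulair
prevacid
prilosec
zantac
miralax
milk of magnesia
diflucan
fluconazole
zithromax
amoxicillin
augmentin
valtrex
acyclovir
ibuprofen
tylenol
l-carnitine
carnosine
l-glutamine
taurine
gaba
5-htp
inositol
coenzyme q10
selenium
iron
potassium
lithium
molybdenum
cromolyn
pepcid
actos
ivig
transfer factor
colostrum
lauricidin
olive leaf extract
grapefruit seed extract
oil of oregano
caprylic acid
candex
threelac
culturelle
kirkman labs supplements
super nu-thera
trace minerals
cilantro
chlorella
bentonite clay
infrared sauna
listening program
interactive metronome
brushing protocol
weighted blanket
weighted vest
service dog
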