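# Closed-class lexicon for the heuristic POS tagger: word TAB coarse tag.
# Coordinators/subordinators carry X (the coarse set has no CONJ tag).
i	PRON
me	PRON
my	PRON
mine	PRON
myself	PRON
we	PRON
us	PRON
our	PRON
ours	PRON
ourselves	PRON
you	PRON
your	PRON
yours	PRON
yourself	PRON
he	PRON
him	PRON
his	PRON
himself	PRON
she	PRON
her	PRON
hers	PRON
herself	PRON
it	PRON
its	PRON
itself	PRON
they	PRON
them	PRON
their	PRON
theirs	PRON
themselves	PRON
who	PRON
whom	PRON
whose	PRON
which	PRON
what	PRON
someone	PRON
anyone	PRON
everyone	PRON
nobody	PRON
something	PRON
anything	PRON
everything	PRON
nothing	PRON
one	PRON
the	DET
a	DET
an	DET
this	DET
that	DET
these	DET
those	DET
each	DET
every	DET
either	DET
neither	DET
some	DET
any	DET
no	DET
all	DET
both	DET
few	DET
several	DET
many	DET
much	DET
most	DET
more	DET
less	DET
another	DET
such	DET
of	ADP
in	ADP
on	ADP
at	ADP
by	ADP
for	ADP
with	ADP
about	ADP
against	ADP
between	ADP
into	ADP
through	ADP
during	ADP
before	ADP
after	ADP
above	ADP
below	ADP
to	ADP
from	ADP
up	ADP
down	ADP
out	ADP
off	ADP
over	ADP
under	ADP
since	ADP
until	ADP
without	ADP
within	ADP
along	ADP
across	ADP
behind	ADP
beyond	ADP
near	ADP
onto	ADP
upon	ADP
toward	ADP
towards	ADP
per	ADP
via	ADP
is	VERB
am	VERB
are	VERB
was	VERB
were	VERB
be	VERB
been	VERB
being	VERB
has	VERB
have	VERB
had	VERB
having	VERB
do	VERB
does	VERB
did	VERB
doing	VERB
will	VERB
would	VERB
shall	VERB
should	VERB
can	VERB
could	VERB
may	VERB
might	VERB
must	VERB
ought	VERB
need	VERB
dare	VERB
not	ADV
n't	ADV
never	ADV
always	ADV
often	ADV
sometimes	ADV
rarely	ADV
seldom	ADV
now	ADV
then	ADV
here	ADV
there	ADV
again	ADV
already	ADV
still	ADV
yet	ADV
soon	ADV
today	ADV
tomorrow	ADV
yesterday	ADV
very	ADV
too	ADV
quite	ADV
rather	ADV
almost	ADV
just	ADV
only	ADV
even	ADV
also	ADV
maybe	ADV
perhaps	ADV
away	ADV
back	ADV
once	ADV
twice	ADV
daily	ADV
weekly	ADV
anymore	ADV
and	X
or	X
but	X
nor	X
so	X
because	X
although	X
though	X
while	X
if	X
unless	X
whether	X
when	X
where	X
why	X
how	X
as	X
than	X
whereas	X
however	X
therefore	X
moreover	X
meanwhile	X
plus	X
except	X
good	ADJ
bad	ADJ
new	ADJ
old	ADJ
little	ADJ
big	ADJ
small	ADJ
same	ADJ
other	ADJ
own	ADJ
last	ADJ
next	ADJ
first	ADJ
second	ADJ
third	ADJ
young	ADJ
high	ADJ
low	ADJ
long	ADJ
short	ADJ
great	ADJ
sure	ADJ
certain	ADJ
whole	ADJ
happy	ADJ
hard	ADJ
easy	ADJ
free	ADJ
fine	ADJ
better	ADJ
worse	ADJ
best	ADJ
worst	ADJ
able	ADJ
glad	ADJ
helpful	ADJ
scientific	ADJ
medical	ADJ
natural	ADJ
mild	ADJ
severe	ADJ
one	NUM
two	NUM
three	NUM
four	NUM
five	NUM
six	NUM
seven	NUM
eight	NUM
nine	NUM
ten	NUM
zero	NUM
hundred	NUM
thousand	NUM
million	NUM
half	NUM
dozen	NUM
yes	X
okay	X
ok	X
hi	X
hello	X
thanks	X
please	X
oh	X
wow	X
hmm	X
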