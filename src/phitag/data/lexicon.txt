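a
account
acute
address
admitted
after
all
alone
and
annual
answered
any
append
are
as
aspirin
assigned
at
attending
available
b
bedside
blood
break
by
c
call
care
cat
categories
change
choice
choices
chosen
clinic
code
condition
config
confirmed
contact
continue
continued
controlled
conventions
corpus
cosigned
currently
d
daily
days
detail
deterministic
dict
discharge
discharged
discontinue
discussed
distress
doc
dose
drawn
earlier
entirely
enumerate
evaluated
evaluation
exam
examination
examined
false
family
file
follow
for
fp
from
generator
get
good
heart
history
home
hospital
hypertension
id
identifier
if
imaging
immediate
in
institution
insulin
int
intake
integers
is
j
k
knobs
labs
last
len
length
limits
list
listed
lives
mailing
medical
medication
medications
mg
months
n
needed
negative
new
no
normal
note
noted
notes
number
of
office
old
on
one
oral
otherwise
outside
overlapping
overnight
pair
patient
patients
performed
pharmacy
phi
phispan
phone
physical
placed
plan
pleasant
please
portal
posted
preds
presents
pressure
previously
prn
progress
questions
radiology
raise
rate
reconciled
record
records
reference
registration
relocated
remains
replace
report
requested
resides
results
return
review
reviewed
rng
routine
scheduling
seen
setdefault
signs
sites
size
skipped
sorted
stable
str
style
surface
surrogate
symptoms
systems
tablet
text
the
therapy
this
to
today
together
top
transferred
tuple
untouched
up
updated
urgent
used
valueerror
verified
visit
vital
vocabularies
was
week
weeks
well
were
will
with
within
without
x
y
year
zip
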