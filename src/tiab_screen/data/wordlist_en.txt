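# Starter English reference wordlist (one word per line, replaceable).
# Any one-word-per-line file (e.g. a full Grady-Ward-style list) may be
# substituted via configuration; matching is stem-to-stem.
abstract
acute
adjust
adult
adverse
age
aim
allocate
analysis
analyze
animal
approach
assess
assign
associate
association
baseline
behavior
benefit
bias
binary
blind
blood
body
cancer
care
case
cause
cell
change
child
chronic
citation
classify
clinical
cohort
compare
comparison
complete
compute
conclude
conclusion
condition
conduct
confidence
confirm
control
correlate
criterion
cross
data
database
death
decide
decision
decrease
define
design
detect
determine
develop
diagnose
diagnosis
difference
disease
dose
double
drug
duration
effect
effective
efficacy
eligible
enroll
estimate
evaluate
event
evidence
examine
exclude
exclusion
exposure
factor
female
finding
follow
frequency
group
guideline
health
heart
high
hospital
human
identify
impact
implement
improve
incidence
include
inclusion
increase
infant
infect
infection
influence
inform
information
intervention
interview
investigate
involve
level
literature
low
male
manage
management
measure
mechanism
medical
medicine
method
model
moderate
monitor
mortality
network
number
observe
obtain
outcome
paper
participant
patient
perform
period
placebo
population
positive
predict
pregnancy
prevalence
prevent
primary
procedure
process
program
progress
propose
prospective
protocol
provide
publication
publish
quality
random
randomize
rate
ratio
receive
record
recruit
reduce
regression
relate
relative
relevant
report
research
respond
response
result
retrospective
review
risk
safety
sample
score
screen
search
secondary
select
sensitivity
severe
show
significant
single
size
specific
standard
statistical
strategy
study
subject
suggest
support
surgery
survey
survival
symptom
syndrome
systematic
test
therapy
time
treat
treatment
trial
type
value
variable
week
weight
woman
year
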