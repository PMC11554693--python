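# Demo adverse-event term list (MedDRA-LLT style, permissively licensed).
# One term per line; the licensed MedDRA vocabulary is user-supplied.
headache
nausea
vomiting
dizziness
rash
pruritus
fatigue
insomnia
somnolence
diarrhea
constipation
dyspnea
cough
pyrexia
abscess
anemia
arthralgia
myalgia
alopecia
tachycardia
bradycardia
hypertension
hypotension
syncope
tremor
vertigo
tinnitus
urticaria
paresthesia
dysgeusia
epistaxis
palpitations
chest discomfort
chest pain
blood pressure
pressure
cardio-respiratory arrest
splenomegaly
cholelithiasis
dehydration
fracture
hepatotoxicity
neutropenia
thrombocytopenia
pancreatitis
angioedema
anaphylaxis
dry mouth
blurred vision
weight decreased
all
high
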