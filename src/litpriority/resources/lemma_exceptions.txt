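# Irregular lemma lexicon: "<surface> <lemma>" pairs, one per line.
# Consulted before the suffix rules in preprocess.lemmatize.
analyses analysis
viruses virus
coronaviruses coronavirus
statuses status
censuses census
bacteria bacterium
bases base
children child
crises crisis
criteria criterion
data data
diagnoses diagnosis
feet foot
fungi fungus
genera genus
hypotheses hypothesis
indices index
lice louse
matrices matrix
media medium
men man
mice mouse
nuclei nucleus
people person
phenomena phenomenon
prognoses prognosis
sera serum
species species
stimuli stimulus
teeth tooth
theses thesis
vertebrae vertebra
viri virus
women woman
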