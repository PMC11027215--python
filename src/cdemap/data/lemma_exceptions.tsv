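men	man
women	woman
children	child
feet	foot
teeth	tooth
geese	goose
mice	mouse
lives	life
wives	wife
knives	knife
leaves	leaf
halves	half
selves	self
shelves	shelf
indices	index
vertices	vertex
matrices	matrix
appendices	appendix
diagnoses	diagnosis
analyses	analysis
prognoses	prognosis
stenoses	stenosis
scleroses	sclerosis
psychoses	psychosis
neuroses	neurosis
crises	crisis
theses	thesis
hypotheses	hypothesis
bases	basis
axes	axis
foci	focus
nuclei	nucleus
gyri	gyrus
sulci	sulcus
radii	radius
stimuli	stimulus
criteria	criterion
phenomena	phenomenon
ganglia	ganglion
bacteria	bacterium
series	series
species	species
lenses	lens
gases	gas
buses	bus
viruses	virus
statuses	status
plexuses	plexus
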