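# Curated synonym -> canonical compound mapping for common primary metabolites.
# Extend or override with a user mapping file (same two-column TSV format).
# synonym	canonical
alanine	alanine
l-alanine	alanine
ala	alanine
beta-alanine	beta-alanine
b-alanine	beta-alanine
arginine	arginine
l-arginine	arginine
asparagine	asparagine
l-asparagine	asparagine
aspartate	aspartate
aspartic acid	aspartate
l-aspartate	aspartate
l-aspartic acid	aspartate
cysteine	cysteine
l-cysteine	cysteine
glutamate	glutamate
glutamic acid	glutamate
l-glutamate	glutamate
l-glutamic acid	glutamate
glutamine	glutamine
l-glutamine	glutamine
glycine	glycine
gly	glycine
histidine	histidine
l-histidine	histidine
isoleucine	isoleucine
l-isoleucine	isoleucine
leucine	leucine
l-leucine	leucine
lysine	lysine
l-lysine	lysine
methionine	methionine
l-methionine	methionine
phenylalanine	phenylalanine
l-phenylalanine	phenylalanine
proline	proline
l-proline	proline
serine	serine
l-serine	serine
threonine	threonine
l-threonine	threonine
tryptophan	tryptophan
l-tryptophan	tryptophan
tyrosine	tyrosine
l-tyrosine	tyrosine
valine	valine
l-valine	valine
ornithine	ornithine
l-ornithine	ornithine
citrulline	citrulline
l-citrulline	citrulline
gaba	4-aminobutyrate
4-aminobutyrate	4-aminobutyrate
4-aminobutyric acid	4-aminobutyrate
gamma-aminobutyrate	4-aminobutyrate
gamma-aminobutyric acid	4-aminobutyrate
homoserine	homoserine
o-acetylserine	o-acetylserine
sarcosine	sarcosine
n-methylglycine	sarcosine
pyroglutamate	pyroglutamate
5-oxoproline	pyroglutamate
pyroglutamic acid	pyroglutamate
citrate	citrate
citric acid	citrate
isocitrate	isocitrate
isocitric acid	isocitrate
aconitate	aconitate
cis-aconitate	aconitate
cis-aconitic acid	aconitate
2-oxoglutarate	2-oxoglutarate
2-oxoglutaric acid	2-oxoglutarate
alpha-ketoglutarate	2-oxoglutarate
alpha-ketoglutaric acid	2-oxoglutarate
a-ketoglutarate	2-oxoglutarate
2-ketoglutaric acid	2-oxoglutarate
akg	2-oxoglutarate
succinate	succinate
succinic acid	succinate
fumarate	fumarate
fumaric acid	fumarate
malate	malate
malic acid	malate
l-malate	malate
oxaloacetate	oxaloacetate
oxaloacetic acid	oxaloacetate
pyruvate	pyruvate
pyruvic acid	pyruvate
lactate	lactate
lactic acid	lactate
l-lactate	lactate
glycolate	glycolate
glycolic acid	glycolate
glyoxylate	glyoxylate
glyoxylic acid	glyoxylate
glycerate	glycerate
glyceric acid	glycerate
d-glycerate	glycerate
hydroxypyruvate	hydroxypyruvate
3-phosphoglycerate	3-phosphoglycerate
3-pga	3-phosphoglycerate
glycerate-3-phosphate	3-phosphoglycerate
2-phosphoglycolate	2-phosphoglycolate
phosphoglycolate	2-phosphoglycolate
phosphoenolpyruvate	phosphoenolpyruvate
pep	phosphoenolpyruvate
shikimate	shikimate
shikimic acid	shikimate
quinate	quinate
quinic acid	quinate
benzoate	benzoate
benzoic acid	benzoate
salicylate	salicylate
salicylic acid	salicylate
ascorbate	ascorbate
ascorbic acid	ascorbate
vitamin c	ascorbate
dehydroascorbate	dehydroascorbate
threonate	threonate
threonic acid	threonate
oxalate	oxalate
oxalic acid	oxalate
malonate	malonate
malonic acid	malonate
maleate	maleate
maleic acid	maleate
tartrate	tartrate
tartaric acid	tartrate
nicotinate	nicotinate
nicotinic acid	nicotinate
niacin	nicotinate
glucose	glucose
d-glucose	glucose
dextrose	glucose
fructose	fructose
d-fructose	fructose
galactose	galactose
d-galactose	galactose
mannose	mannose
d-mannose	mannose
sucrose	sucrose
maltose	maltose
trehalose	trehalose
raffinose	raffinose
xylose	xylose
d-xylose	xylose
arabinose	arabinose
l-arabinose	arabinose
ribose	ribose
d-ribose	ribose
rhamnose	rhamnose
fucose	fucose
gentiobiose	gentiobiose
melibiose	melibiose
isomaltose	isomaltose
cellobiose	cellobiose
glucose-6-phosphate	glucose-6-phosphate
g6p	glucose-6-phosphate
fructose-6-phosphate	fructose-6-phosphate
f6p	fructose-6-phosphate
glucose-1-phosphate	glucose-1-phosphate
glucuronate	glucuronate
glucuronic acid	glucuronate
galacturonate	galacturonate
galacturonic acid	galacturonate
gluconate	gluconate
gluconic acid	gluconate
glycerol	glycerol
glycerol-3-phosphate	glycerol-3-phosphate
myo-inositol	myo-inositol
inositol	myo-inositol
meso-inositol	myo-inositol
mannitol	mannitol
d-mannitol	mannitol
sorbitol	sorbitol
d-sorbitol	sorbitol
glucitol	sorbitol
galactinol	galactinol
erythritol	erythritol
xylitol	xylitol
ribitol	ribitol
adonitol	ribitol
threitol	threitol
putrescine	putrescine
1,4-diaminobutane	putrescine
spermidine	spermidine
spermine	spermine
ethanolamine	ethanolamine
monoethanolamine	ethanolamine
tyramine	tyramine
dopamine	dopamine
adenine	adenine
adenosine	adenosine
guanine	guanine
guanosine	guanosine
uracil	uracil
uridine	uridine
thymine	thymine
cytosine	cytosine
inosine	inosine
hypoxanthine	hypoxanthine
xanthine	xanthine
allantoin	allantoin
urea	urea
uric acid	urate
urate	urate
phosphate	phosphate
orthophosphate	phosphate
inorganic phosphate	phosphate
sinapate	sinapate
sinapic acid	sinapate
ferulate	ferulate
ferulic acid	ferulate
caffeate	caffeate
caffeic acid	caffeate
chlorogenate	chlorogenate
chlorogenic acid	chlorogenate
fructose-1,6-bisphosphate	fructose-1,6-bisphosphate
ribulose-5-phosphate	ribulose-5-phosphate
ribose-5-phosphate	ribose-5-phosphate
sedoheptulose-7-phosphate	sedoheptulose-7-phosphate
trehalose-6-phosphate	trehalose-6-phosphate
citramalate	citramalate
citramalic acid	citramalate
2-hydroxyglutarate	2-hydroxyglutarate
2-hydroxyglutaric acid	2-hydroxyglutarate
3-hydroxybutyrate	3-hydroxybutyrate
3-hydroxybutyric acid	3-hydroxybutyrate
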