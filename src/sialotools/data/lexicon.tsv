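term	class	family	priority
kunitz	secreted	Kunitz	3
kazal	secreted	Kazal	3
cystatin	secreted	Cystatin	3
serpin	secreted	Serpin	3
serine protease inhibitor	secreted	Serpin	2
trypsin inhibitor	secreted	TIL	3
trypsin-inhibitor	secreted	TIL	3
til domain	secreted	TIL	3
antigen 5	secreted	Antigen-5	1
antigen-5	secreted	Antigen-5	1
venom allergen	secreted	Antigen-5	1
apolipoprotein	secreted	Apolipoprotein	1
amylase	secreted	Amylase	1
maltase	secreted	Maltase	1
alpha-glucosidase	secreted	Maltase	1
acid phosphatase	secreted	Acid phosphatase	1
cysteine peptidase	secreted	Cysteine peptidase	1
cysteine protease	secreted	Cysteine peptidase	1
cathepsin	secreted	Cysteine peptidase	1
dipeptidyl peptidase	secreted	Dipeptidyl peptidase	1
metallopeptidase	secreted	Metallo peptidase	1
metalloprotease	secreted	Metallo peptidase	1
metallo peptidase	secreted	Metallo peptidase	1
serine peptidase	secreted	Serine peptidase	1
serine protease	secreted	Serine peptidase	1
trypsin	secreted	Serine peptidase	1
chymotrypsin	secreted	Serine peptidase	1
esterase	secreted	Esterase	1
lipase	secreted	Lipase	1
hormone-binding protein	secreted	Hormone-binding protein	1
hormone binding protein	secreted	Hormone-binding protein	1
attacin	secreted	Attacin	1
lectin	secreted	Lectin	1
diptericin	secreted	Diptericin	1
cecropin	secreted	Cecropin	1
lysozyme	secreted	Lysozyme	1
defensin	secreted	Defensin	1
mucin	secreted	Mucin	1
odorant-binding	secreted	Odorant-binding protein	1
odorant binding	secreted	Odorant-binding protein	1
salivary secreted protein	secreted	Unknown	1
cytochrome c oxidase	Met/Energy		0
nadh dehydrogenase	Met/Energy		0
atp synthase	Met/Energy		0
citrate synthase	Met/Energy		0
succinate dehydrogenase	Met/Energy		0
malate dehydrogenase	Met/Energy		0
rna polymerase	transcription machinery		0
transcription factor	transcription machinery		0
transcription initiation	transcription machinery		0
mediator complex	transcription machinery		0
ribosomal protein	protein synthesis		0
elongation factor	protein synthesis		0
translation initiation factor	protein synthesis		0
aminoacyl-trna synthetase	protein synthesis		0
glycosyltransferase	protein modification		0
protein disulfide isomerase	protein modification		0
peptidylprolyl isomerase	protein modification		0
signal recognition particle	protein export		0
sec61	protein export		0
translocon	protein export		0
proteasome	proteasome		0
ubiquitin	proteasome		0
abc transporter	transporter		0
solute carrier	transporter		0
aquaporin	transporter		0
monocarboxylate transporter	transporter		0
actin	cytoskeletal		0
tubulin	cytoskeletal		0
myosin	cytoskeletal		0
dynein	cytoskeletal		0
protein kinase	signal transduction		0
protein phosphatase	signal transduction		0
gtpase	signal transduction		0
g protein	signal transduction		0
importin	nuclear regulation		0
exportin	nuclear regulation		0
nucleoporin	nuclear regulation		0
peptidoglycan recognition	immunity		0
toll receptor	immunity		0
immune deficiency	immunity		0
prophenoloxidase	immunity		0
glyceraldehyde-3-phosphate	carbohydrate metabolism		0
enolase	carbohydrate metabolism		0
pyruvate kinase	carbohydrate metabolism		0
glycogen phosphorylase	carbohydrate metabolism		0
fatty acid synthase	lipid metabolism		0
lipophorin	lipid metabolism		0
acyl-coa dehydrogenase	lipid metabolism		0
aminotransferase	amino acid metabolism		0
glutamine synthetase	amino acid metabolism		0
arginase	amino acid metabolism		0
thymidylate synthase	nucleotide metabolism		0
ribonucleotide reductase	nucleotide metabolism		0
adenylate kinase	nucleotide metabolism		0
cytochrome p450	detoxification		0
glutathione s-transferase	detoxification		0
udp-glucuronosyltransferase	detoxification		0
superoxide dismutase	oxidant metabolism		0
catalase	oxidant metabolism		0
thioredoxin	oxidant metabolism		0
peroxiredoxin	oxidant metabolism		0
vitellogenin	storage		0
hexamerin	storage		0
ferritin	storage		0
collagen	extracellular matrix		0
laminin	extracellular matrix		0
peritrophin	extracellular matrix		0
histone	chromatin		0
chromodomain	chromatin		0
transposase	transposable element		0
reverse transcriptase	transposable element		0
gag-pol	transposable element		0
caspase	apoptosis		0
apoptosis inducing	apoptosis		0
inhibitor of apoptosis	apoptosis		0
heat shock protein	chaperone		0
chaperonin	chaperone		0
dnaj	chaperone		0
cyclin	cell cycle		0
cell division cycle	cell cycle		0
spliceosome	RNA processing		0
splicing factor	RNA processing		0
helicase	RNA processing		0
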