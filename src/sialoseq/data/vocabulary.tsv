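keyword	class_label	subfamily
lipocalin	Secreted	Lipocalin
triabin	Secreted	Lipocalin
pallidipin	Secreted	Lipocalin
procalin	Secreted	Lipocalin
nitrophorin	Secreted	Lipocalin
trialysin	Secreted	Trialysin
apyrase	Secreted	Apyrase
5' nucleotidase	Secreted	Apyrase
kazal	Secreted	Kazal peptide
pacifastin	Secreted	Pacifastin
protease inhibitor	Secreted	Protease inhibitor
antigen 5	Secreted	Antigen 5
odorant binding	Secreted	Odorant binding protein
pheromone binding	Secreted	Odorant binding protein
defensin	Secreted	Defensin
diptericin	Secreted	Diptericin
attacin	Secreted	Attacin
lysozyme	Secreted	Lysozyme
ggy	Secreted	GGY family
mucin	Secreted	Mucin
c-type lectin	Secreted	C-type lectin
serine protease	Secreted	Protease
metalloprotease	Secreted	Protease
asparaginyl peptidase	Secreted	Protease
cathepsin	Secreted	Protease
trypsin	Secreted	Protease
inositol phosphatase	Secreted	Phosphatase
rna-directed rna polymerase	Viral
nonstructural protein	Viral
capsid	Viral
coat protein	Viral
virus	Viral
viral	Viral
reverse transcriptase	Transposable element
transposase	Transposable element
retrotransposon	Transposable element
transposon	Transposable element
gag-pol	Transposable element
pol polyprotein	Transposable element
copia	Transposable element
gypsy	Transposable element
mariner	Transposable element
cuticular protein	Housekeeping	Extracellular matrix
collagen	Housekeeping	Extracellular matrix
laminin	Housekeeping	Extracellular matrix
juvenile hormone	Housekeeping	Metabolism
cytochrome p450	Housekeeping	Detoxification
chorion peroxidase	Housekeeping	Detoxification
peroxidase	Housekeeping	Detoxification
glutathione	Housekeeping	Detoxification
doublesex	Housekeeping	Transcription factor
transcription factor	Housekeeping	Transcription factor
histone	Housekeeping	Nuclear regulation
deacetylase	Housekeeping	Nuclear regulation
sirtuin	Housekeeping	Nuclear regulation
methyltransferase	Housekeeping	Protein modification
heat shock	Housekeeping	Protein modification
chaperon	Housekeeping	Protein modification
vitellogenin	Housekeeping	Storage
hexamerin	Housekeeping	Storage
ribosomal protein	Housekeeping	Protein synthesis machinery
elongation factor	Housekeeping	Protein synthesis machinery
ubiquitin	Housekeeping	Proteasome machinery
proteasome	Housekeeping	Proteasome machinery
tubulin	Housekeeping	Cytoskeletal
actin	Housekeeping	Cytoskeletal
myosin	Housekeeping	Cytoskeletal
importin	Housekeeping	Nuclear export
exportin	Housekeeping	Nuclear export
nucleoporin	Housekeeping	Protein export
signal peptidase	Housekeeping	Protein export
rna polymerase	Housekeeping	Transcription machinery
helicase	Housekeeping	Transcription machinery
atp synthase	Housekeeping	Metabolism
cytochrome c oxidase	Housekeeping	Metabolism
dehydrogenase	Housekeeping	Metabolism
aminotransferase	Housekeeping	Amino acid metabolism
lipase	Housekeeping	Lipid metabolism
fatty acid	Housekeeping	Lipid metabolism
kinase	Housekeeping	Signal transduction
phosphatase	Housekeeping	Signal transduction
g protein	Housekeeping	Signal transduction
transporter	Housekeeping	Transporters and channels
ion channel	Housekeeping	Transporters and channels
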