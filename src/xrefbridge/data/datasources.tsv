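syscode	full_name	miriam_base	url_pattern	entity_category	id_example
En	Ensembl	ensembl	https://www.ensembl.org/id/$id	gene	ENSG00000122375
L	Entrez Gene	entrez.gene	https://www.ncbi.nlm.nih.gov/gene/$id	gene	3643
S	UniProt	uniprot	https://www.uniprot.org/uniprot/$id	protein	P62158
U	UniGene	unigene	https://www.ncbi.nlm.nih.gov/unigene/?term=$id	gene	Hs.654587
Q	RefSeq	refseq	https://www.ncbi.nlm.nih.gov/protein/$id	gene	NM_000207
Mb	miRBase	mirbase	https://www.mirbase.org/hairpin/$id	gene	MI0000060
Pd	PDB	pdb	https://www.rcsb.org/structure/$id	protein	1CLL
X	Affymetrix	affy.probeset	https://www.affymetrix.com/LinkServlet?probeset=$id	probe	1858_at
Ag	Agilent			probe	A_23_P69058
Il	Illumina			probe	ILMN_1764609
Ca	CAS	cas	https://commonchemistry.cas.org/detail?cas_rn=$id	metabolite	50-00-0
Ce	ChEBI	chebi	https://www.ebi.ac.uk/chebi/searchId.do?chebiId=$id	metabolite	CHEBI:17234
Cp	PubChem Compound	pubchem.compound	https://pubchem.ncbi.nlm.nih.gov/compound/$id	metabolite	5793
Ck	KEGG Compound	kegg.compound	https://www.genome.jp/dbget-bin/www_bget?$id	metabolite	C00031
Ch	HMDB	hmdb	https://hmdb.ca/metabolites/$id	metabolite	HMDB00122
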