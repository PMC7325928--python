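otu_id	domain	phylum	class	order	family	genus	species
OTU01	Bacteria	Proteobacteria	Alphaproteobacteria	Rickettsiales	Midichloriaceae	Candidatus Midichloria	endosymbiont
OTU02	Bacteria	Proteobacteria	Alphaproteobacteria	Rickettsiales	Rickettsiaceae	Rickettsia	unknown
OTU03	Bacteria	Firmicutes	Bacilli	Bacillales	Bacillaceae	Bacillus	unknown
OTU04	Bacteria	Proteobacteria	Gammaproteobacteria	Pseudomonadales	Pseudomonadaceae	Pseudomonas	unknown
OTU05	Bacteria	Proteobacteria	Gammaproteobacteria	Pseudomonadales	Moraxellaceae	Acinetobacter	unknown
OTU06	Bacteria	Proteobacteria	Gammaproteobacteria	Oceanospirillales	Halomonadaceae	Halomonas	unknown
OTU07	Bacteria	Proteobacteria	Alphaproteobacteria	Rickettsiales	Mitochondria	unknown	unknown
OTU08	Bacteria	Cyanobacteria	Oxyphotobacteria	Chloroplast	unknown	unknown	unknown
OTU09	unknown	unknown	unknown	unknown	unknown	unknown	unknown
OTU10	Bacteria	Actinobacteria	Actinomycetia	Micrococcales	Micrococcaceae	Micrococcus	unknown
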