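genus	group	recommended
Agaricus	1	
Antherospora	1	
Antrodia	1	
Ceriporiopsis	1	
Chroogomphus	1	
Clavaria	1	
Coprinopsis	1	
Cystodermella	1	
Datronia	1	
Endoraecium	1	
Entoloma	1	
Entyloma	1	
Exobasidium	1	
Favolus	1	
Fibroporia	1	
Fuscoporia	1	
Geastrum	1	
Gloeophyllum	1	
Helicobasidium	1	
Hygrocybe	1	
Hymenopellis	1	
Hyphodermella	1	
Lactifluus	1	
Lepiota	1	
Lepista	1	
Leucopaxillus	1	
Lycoperdon	1	
Lyomyces	1	
Lyophyllum	1	
Melampsora	1	
Neofavolus	1	
Octaviania	1	
Oligoporus	1	
Phanerochaete	1	
Phellinus	1	
Phellodon	1	
Piloderma	1	
Polyporus	1	
Porodaedalea	1	
Psathyrella	1	
Psilocybe	1	
Puccinia	1	
Pycnoporellus	1	
Resinicium	1	
Rhodocollybia	1	
Russula	1	
Sarcodon	1	
Suillus	1	
Thelephora	1	
Thecaphora	1	
Tilletia	1	
Tricholomopsis	1	
Xerocomus	1	
Xeromphalina	1	
Amanita	2	ITS2
Amyloporia	2	ITS2
Antrodiella	2	ITS,ITS2
Auricularia	2	ITS
Calvatia	2	ITS,ITS1
Chlorophyllum	2	ITS,ITS1
Flammulina	2	ITS
Fomitopsis	2	ITS2
Ganoderma	2	ITS,ITS1
Gymnopilus	2	ITS,ITS1
Gymnopus	2	ITS,ITS1
Hygrophorus	2	ITS1
Lentinellus	2	ITS
Leucoagaricus	2	ITS,ITS1
Macrolepiota	2	ITS,ITS1
Megacollybia	2	ITS,ITS1
Microbotryum	2	ITS
Parasola	2	ITS
Postia	2	ITS,ITS2
Rigidoporus	2	ITS,ITS1
Scleroderma	2	ITS2
Stephanospora	2	ITS1
Strobilurus	2	ITS2
Tuberculina	2	ITS
Alnicola	3	
Armillaria	3	
Boletus	3	
Collybia	3	
Cortinarius	3	
Cystoderma	3	
Hebeloma	3	
Hydnellum	3	
Hyphoderma	3	
Hypholoma	3	
Inocybe	3	
Lentinus	3	
Melanoleuca	3	
Mycena	3	
Paxillus	3	
Pleurotus	3	
Pluteus	3	
Ramaria	3	
Rhizopogon	3	
Sebacina	3	
Tomentella	3	
Tricholoma	3	
Trametes	3	
Vuilleminia	3	
Butyriboletus	4	
Clavulina	4	
Crepidotus	4	
Hohenbuehelia	4	
Hydnum	4	
Laccaria	4	
Lactarius	4	
Mucidula	4	
Peniophorella	4	
Phaeocollybia	4	
Pisolithus	4	
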