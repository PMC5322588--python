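genus	pci_its	pci_its1	pci_its2
Agaricus	100	100	100
Alnicola	44	33	33
Amanita	24	27	27
Amyloporia	25	25	25
Antherospora	100	100	100
Antrodia	70	70	70
Antrodiella	75	50	75
Armillaria	20	20	20
Auricularia	80	40	60
Boletus	32	26	47
Butyriboletus	67	33	67
Calvatia	0	0	0
Ceriporiopsis	100	100	100
Chlorophyllum	100	100	100
Chroogomphus	50	50	50
Clavaria	100	100	100
Clavulina	33	33	33
Collybia	50	50	50
Coprinopsis	50	50	50
Cortinarius	36	45	37
Crepidotus	50	50	50
Cystoderma	50	50	33
Cystodermella	100	100	100
Datronia	0	50	0
Endoraecium	100	100	100
Entoloma	100	86	93
Entyloma	100	100	100
Exobasidium	100	100	100
Favolus	100	100	100
Fibroporia	100	100	67
Flammulina	100	50	75
Fomitopsis	50	25	50
Fuscoporia	100	100	100
Ganoderma	43	43	43
Geastrum	100	67	67
Gloeophyllum	100	100	100
Gymnopilus	100	100	50
Gymnopus	67	67	60
Hebeloma	42	37	32
Helicobasidium	100	75	100
Hohenbuehelia	0	0	0
Hydnellum	56	56	56
Hydnum	50	50	50
Hygrocybe	0	0	0
Hygrophorus	67	67	33
Hymenopellis	100	100	100
Hyphoderma	60	60	80
Hyphodermella	100	100	100
Hypholoma	0	0	0
Inocybe	30	19	28
Laccaria	0	0	13
Lactarius	37	37	41
Lactifluus	50	50	50
Lentinellus	43	43	29
Lentinus	57	57	71
Lepiota	92	83	75
Lepista	100	100	100
Leucoagaricus	90	100	80
Leucopaxillus	100	100	100
Lycoperdon	100	100	100
Lyomyces	100	100	100
Lyophyllum	100	100	67
Macrolepiota	50	50	33
Megacollybia	83	83	33
Melampsora	40	40	20
Melanoleuca	38	38	25
Microbotryum	70	80	50
Mucidula	0	0	0
Mycena	22	22	33
Neofavolus	100	100	100
Octaviania	100	100	100
Oligoporus	100	100	100
Parasola	100	67	67
Paxillus	0	0	33
Peniophorella	50	50	50
Phaeocollybia	0	0	0
Phanerochaete	67	67	67
Phellinus	100	33	67
Phellodon	86	86	71
Piloderma	50	50	50
Pisolithus	0	0	0
Pleurotus	29	43	14
Pluteus	27	27	23
Polyporus	100	100	86
Porodaedalea	100	100	100
Postia	50	50	50
Psathyrella	100	100	100
Psilocybe	100	100	100
Puccinia	43	43	43
Pycnoporellus	100	100	100
Ramaria	33	33	33
Resinicium	100	100	100
Rhizopogon	27	27	27
Rhodocollybia	100	100	100
Rigidoporus	100	100	50
Russula	38	27	36
Sarcodon	86	86	86
Scleroderma	33	33	33
Sebacina	33	0	33
Stephanospora	80	80	20
Strobilurus	67	67	67
Suillus	83	83	83
Thecaphora	100	100	100
Thelephora	0	0	0
Tilletia	100	33	100
Tomentella	25	50	25
Trametes	42	42	42
Tricholoma	43	57	29
Tricholomopsis	100	100	100
Tuberculina	67	0	67
Vuilleminia	33	33	33
Xerocomus	100	50	100
Xeromphalina	100	100	50
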