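state_id	cell_type	driving_cytokines	marker_genes
B-a	B cell	IFN-α1;IFN-β;IFN-ε;IFN-κ	
B-b	B cell	IFN-γ;IL-2;IL-12;IL-15;IL-18	
B-c	B cell	IL-1α;IL-1β	
B-d	B cell	TNF-α	
B-e	B cell	IL-4	
T4-a	CD4 T cell	IFN-α1;IFN-β;IFN-ε;IFN-κ	
T4-b	CD4 T cell	IFN-γ;IL-2;IL-12;IL-15;IL-18	
T4-c	CD4 T cell	IL-1α;IL-1β	
T4-d	CD4 T cell	TNF-α	
T4-e	CD4 T cell	IL-4	
T8-a	CD8 T cell	IFN-α1;IFN-β;IFN-ε;IFN-κ	
T8-b	CD8 T cell	IFN-γ;IL-2;IL-12;IL-15;IL-18	
T8-c	CD8 T cell	IL-1α;IL-1β	
T8-d	CD8 T cell	TNF-α	
T8-e	CD8 T cell	IL-2	
T8-f	CD8 T cell	IL-21	
Tgd-a	gd T cell	IFN-α1;IFN-β;IFN-ε;IFN-κ	
Tgd-b	gd T cell	IFN-γ;IL-2;IL-12;IL-15;IL-18	
Tgd-c	gd T cell	IL-1α;IL-1β	
Tgd-d	gd T cell	TNF-α	
Treg-a	Treg	IFN-α1;IFN-β;IFN-ε;IFN-κ	
Treg-b	Treg	IFN-γ;IL-2;IL-12;IL-15;IL-18	
Treg-c	Treg	IL-1α;IL-1β	
Treg-d	Treg	TNF-α	
NK-a	NK cell	IFN-α1;IFN-β;IFN-ε;IFN-κ	
NK-b	NK cell	IFN-γ;IL-2;IL-12;IL-15;IL-18	
NK-c	NK cell	IL-1α;IL-1β	
NK-d	NK cell	TNF-α	
NK-e	NK cell	IL-4	
ILC-a	ILC	IFN-α1;IFN-β;IFN-ε;IFN-κ	
ILC-b	ILC	IFN-γ;IL-2;IL-12;IL-15;IL-18	
ILC-c	ILC	IL-1α;IL-1β	
ILC-d	ILC	TNF-α	
Mac-a	Macrophage	IFN-α1;IFN-β;IFN-ε;IFN-κ	
Mac-b	Macrophage	IFN-γ;IL-2;IL-12;IL-15;IL-18	
Mac-c	Macrophage	IL-1α;IL-1β	
Mac-d	Macrophage	TNF-α	
Mac-e	Macrophage	IL-4;IL-13	
Mono-a	Monocyte	IFN-α1;IFN-β;IFN-ε;IFN-κ	
Mono-b	Monocyte	IFN-γ;IL-2;IL-12;IL-15;IL-18	
Mono-c	Monocyte	IL-1α;IL-1β	
Mono-d	Monocyte	TNF-α	
Mono-e	Monocyte	IL-4	
Neu-a	Neutrophil	IFN-α1;IFN-β;IFN-ε;IFN-κ	
Neu-b	Neutrophil	IFN-γ;IL-2;IL-12;IL-15;IL-18	
Neu-c	Neutrophil	IL-1α;IL-1β	
Neu-d	Neutrophil	TNF-α	
Neu-e	Neutrophil	IL-4	
DC1-a	cDC1	IFN-α1;IFN-β;IFN-ε;IFN-κ	
DC1-b	cDC1	IFN-γ;IL-2;IL-12;IL-15;IL-18	
DC1-c	cDC1	IL-1α;IL-1β	
DC1-d	cDC1	TNF-α	
DC2-a	cDC2	IFN-α1;IFN-β;IFN-ε;IFN-κ	
DC2-b	cDC2	IFN-γ;IL-2;IL-12;IL-15;IL-18	
DC2-c	cDC2	IL-1α;IL-1β	
DC2-d	cDC2	TNF-α	
DC2-e	cDC2	IL-4	
pDC-a	pDC	IFN-α1;IFN-β;IFN-ε;IFN-κ	
pDC-b	pDC	IFN-γ;IL-2;IL-12;IL-15;IL-18	
pDC-c	pDC	IL-1α;IL-1β	
pDC-d	pDC	TNF-α	
pDC-e	pDC	IL-4	
LC-a	Langerhans cell	IFN-α1;IFN-β;IFN-ε;IFN-κ	
LC-b	Langerhans cell	IFN-γ;IL-2;IL-12;IL-15;IL-18	
LC-c	Langerhans cell	IL-1α;IL-1β	
LC-d	Langerhans cell	TNF-α	
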