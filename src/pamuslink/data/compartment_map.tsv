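term	compartment
chloroplast	plastid
plastid	plastid
thylakoid membrane	membrane
plasma membrane	membrane
cell membrane	membrane
membrane	membrane
mitochondrion	mitochondrion
mitochondrial	mitochondrion
endoplasmic reticulum	endoplasmic reticulum
cytosol	cytoplasm
cytoplasm	cytoplasm
nucleolus	nucleus
nucleus	nucleus
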