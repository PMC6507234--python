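# Default RNA-binding-protein consensus table: protein name <TAB> IUPAC consensus.
# These entries are illustrative defaults in the style of published in-vitro
# consensus compendia; they are user-replaceable and NOT canonical.  Supply
# your own table (--motifs) for any quantitative use.
RBFOX1	TGCATG
HNRNPL	ACACRA
HNRNPA1	TAGGGW
PTBP1	YTCTTC
MATR3	ATCTTM
RBM3	DAYGAR
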