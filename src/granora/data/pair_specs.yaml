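# Six example EcoCyc/KEGG pathway pairings for the granularity comparison.
# Sizes are gene counts per pathway; universe totals are pathway-assigned
# gene counts per database (EcoCyc 1096, KEGG 1686 E. coli genes); the
# correction multipliers are the pathway counts (EcoCyc 354, KEGG 119).
defaults:
  N_fine: 1096
  N_coarse: 1686
  m_fine: 354
  m_coarse: 119
pairs:
  - label: cysteine
    fine_id: CYSTSYN-PWY
    fine_name: L-cysteine biosynthesis
    coarse_id: map00270
    coarse_name: Cysteine and methionine metabolism
    n_fine: 3
    n_coarse: 34
  - label: arginine
    fine_id: ARGSYN-PWY
    fine_name: Arginine biosynthesis
    coarse_id: map00220
    coarse_name: Arginine biosynthesis
    n_fine: 12
    n_coarse: 18
  - label: selenocysteine
    fine_id: PWY0-901
    fine_name: L-selenocysteine biosynthesis I
    coarse_id: map00450
    coarse_name: Selenocompound metabolism
    n_fine: 4
    n_coarse: 17
  - label: valine
    fine_id: VALSYN-PWY
    fine_name: L-valine biosynthesis
    coarse_id: map00290
    coarse_name: Valine, leucine, and isoleucine biosynthesis
    n_fine: 9
    n_coarse: 16
  - label: purine
    fine_id: PWY-7222
    fine_name: Guanosine deoxyribonucleotides de novo biosynthesis II
    coarse_id: map00230
    coarse_name: Purine metabolism
    n_fine: 10
    n_coarse: 78
  - label: pyrimidine
    fine_id: PWY-7184
    fine_name: Pyrimidine deoxyribonucleotides de novo biosynthesis I
    coarse_id: map00240
    coarse_name: Pyrimidine metabolism
    n_fine: 13
    n_coarse: 51
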