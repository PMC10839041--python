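# Genus-level community fixture: per-group relative-abundance targets
# (mean and SD, percent scale). The cholesterol phenotype is coupled
# negatively to the Muribaculum-like genus and positively to the
# Lactococcus-like genus; couplings are target Pearson correlations.
name: genus_table3
level: genus
group_order: [ND, WD, WD-T070]
group_sizes: {ND: 11, WD: 10, WD-T070: 8}
noise_model: gamma_renormalized
taxa:
  - name: uncl. Bifidobacteriaceae
    mean: {ND: 1.05, WD: 0.07, WD-T070: 0.10}
    sd: {ND: 0.58, WD: 0.10, WD-T070: 0.10}
  - name: Bifidobacterium
    mean: {ND: 6.63, WD: 0.30, WD-T070: 0.57}
    sd: {ND: 4.43, WD: 0.38, WD-T070: 0.62}
  - name: uncl. Coriobacteriia
    mean: {ND: 0.03, WD: 0.02, WD-T070: 0.09}
    sd: {ND: 0.03, WD: 0.01, WD-T070: 0.07}
  - name: Bacteroides
    mean: {ND: 0.61, WD: 1.93, WD-T070: 1.74}
    sd: {ND: 0.35, WD: 1.26, WD-T070: 0.89}
  - name: uncl. Bacteroidaceae
    mean: {ND: 0.10, WD: 0.30, WD-T070: 0.45}
    sd: {ND: 0.08, WD: 0.24, WD-T070: 0.16}
  - name: Phocaeicola
    mean: {ND: 0.67, WD: 1.71, WD-T070: 7.79}
    sd: {ND: 0.52, WD: 1.36, WD-T070: 2.29}
  - name: uncl. Muribaculaceae
    mean: {ND: 6.86, WD: 5.39, WD-T070: 7.85}
    sd: {ND: 1.95, WD: 1.20, WD-T070: 1.06}
  - name: Paramuribaculum
    mean: {ND: 0.25, WD: 0.41, WD-T070: 0.01}
    sd: {ND: 0.20, WD: 0.20, WD-T070: 0.01}
  - name: Muribaculum
    mean: {ND: 0.60, WD: 0.13, WD-T070: 0.40}
    sd: {ND: 0.22, WD: 0.03, WD-T070: 0.15}
  - name: Odoribacter
    mean: {ND: 3.78, WD: 2.85, WD-T070: 0.70}
    sd: {ND: 1.89, WD: 1.61, WD-T070: 0.62}
  - name: uncl. Porphyromonadaceae
    mean: {ND: 0.00, WD: 0.02, WD-T070: 0.02}
    sd: {ND: 0.00, WD: 0.02, WD-T070: 0.03}
  - name: Parabacteroides
    mean: {ND: 0.02, WD: 0.24, WD-T070: 1.64}
    sd: {ND: 0.02, WD: 0.18, WD-T070: 1.29}
  - name: uncl. Bacteroidales
    mean: {ND: 4.65, WD: 7.94, WD-T070: 2.38}
    sd: {ND: 1.58, WD: 2.92, WD-T070: 0.66}
  - name: uncl. Bacteroidetes
    mean: {ND: 0.37, WD: 0.32, WD-T070: 0.13}
    sd: {ND: 0.12, WD: 0.12, WD-T070: 0.08}
  - name: uncl. Lactobacillaceae
    mean: {ND: 0.34, WD: 0.15, WD-T070: 0.04}
    sd: {ND: 0.28, WD: 0.22, WD-T070: 0.05}
  - name: Lactococcus
    mean: {ND: 0.98, WD: 4.66, WD-T070: 0.73}
    sd: {ND: 0.92, WD: 2.19, WD-T070: 0.43}
  - name: uncl. Lactobacillales
    mean: {ND: 0.11, WD: 0.19, WD-T070: 0.05}
    sd: {ND: 0.08, WD: 0.07, WD-T070: 0.06}
  - name: Clostridium_XlVa
    mean: {ND: 0.58, WD: 1.32, WD-T070: 1.14}
    sd: {ND: 0.36, WD: 0.54, WD-T070: 0.54}
  - name: Schaedlerella
    mean: {ND: 0.02, WD: 0.38, WD-T070: 0.60}
    sd: {ND: 0.03, WD: 0.26, WD-T070: 0.36}
  - name: Ruthenibacterium
    mean: {ND: 0.01, WD: 0.00, WD-T070: 0.13}
    sd: {ND: 0.02, WD: 0.00, WD-T070: 0.06}
  - name: Oscillibacter
    mean: {ND: 0.22, WD: 0.28, WD-T070: 0.83}
    sd: {ND: 0.16, WD: 0.10, WD-T070: 0.43}
  - name: uncl. Clostridiales
    mean: {ND: 1.87, WD: 2.84, WD-T070: 4.49}
    sd: {ND: 0.87, WD: 1.78, WD-T070: 1.28}
  - name: uncl. Erysipelotrichaceae
    mean: {ND: 25.87, WD: 11.79, WD-T070: 15.50}
    sd: {ND: 4.88, WD: 8.28, WD-T070: 9.24}
  - name: Allobaculum
    mean: {ND: 3.18, WD: 1.58, WD-T070: 1.31}
    sd: {ND: 1.13, WD: 1.14, WD-T070: 0.62}
  - name: uncl. Alphaproteobacteria
    mean: {ND: 0.03, WD: 0.02, WD-T070: 0.55}
    sd: {ND: 0.05, WD: 0.02, WD-T070: 0.58}
  - name: Desulfovibrio
    mean: {ND: 0.64, WD: 0.42, WD-T070: 2.14}
    sd: {ND: 0.50, WD: 0.23, WD-T070: 0.89}
phenotypes:
  - name: cholesterol
    mean: {ND: 100.0, WD: 136.0, WD-T070: 121.0}
    sd: {ND: 12.0, WD: 12.0, WD-T070: 12.0}
couplings:
  - {taxon: Muribaculum, phenotype: cholesterol, r: -0.6}
  - {taxon: Lactococcus, phenotype: cholesterol, r: 0.6}
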