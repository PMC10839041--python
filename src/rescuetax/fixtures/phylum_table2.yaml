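# Phylum-level community fixture: per-group relative-abundance targets
# (mean and SD, percent scale) for the three-group diet-intervention design.
name: phylum_table2
level: phylum
group_order: [ND, WD, WD-T070]
group_sizes: {ND: 11, WD: 10, WD-T070: 8}
noise_model: gamma_renormalized
taxa:
  - name: Actinobacteria
    mean: {ND: 8.50, WD: 0.99, WD-T070: 1.22}
    sd: {ND: 5.43, WD: 0.40, WD-T070: 1.05}
  - name: Firmicutes
    mean: {ND: 56.03, WD: 59.16, WD-T070: 53.07}
    sd: {ND: 5.35, WD: 4.86, WD-T070: 8.78}
  - name: Bacteroidetes
    mean: {ND: 26.14, WD: 30.16, WD-T070: 32.78}
    sd: {ND: 4.44, WD: 6.59, WD-T070: 4.11}
  - name: Verrucomicrobia
    mean: {ND: 3.42, WD: 2.59, WD-T070: 4.76}
    sd: {ND: 4.31, WD: 4.38, WD-T070: 6.62}
  - name: uncl. Bacteria
    mean: {ND: 2.40, WD: 2.11, WD-T070: 2.23}
    sd: {ND: 0.45, WD: 0.18, WD-T070: 0.48}
  - name: Deferribacteres Candidatus
    mean: {ND: 1.88, WD: 2.63, WD-T070: 1.43}
    sd: {ND: 3.92, WD: 4.71, WD-T070: 2.38}
  - name: Saccharibacteria
    mean: {ND: 0.24, WD: 0.29, WD-T070: 0.56}
    sd: {ND: 0.19, WD: 0.36, WD-T070: 0.70}
  - name: Campilobacterota
    mean: {ND: 0.00, WD: 0.00, WD-T070: 0.00}
    sd: {ND: 0.00, WD: 0.01, WD-T070: 0.00}
  - name: Tenericutes
    mean: {ND: 0.06, WD: 0.00, WD-T070: 0.00}
    sd: {ND: 0.09, WD: 0.00, WD-T070: 0.00}
  - name: Proteobacteria
    mean: {ND: 1.33, WD: 2.07, WD-T070: 3.93}
    sd: {ND: 1.04, WD: 1.29, WD-T070: 1.38}
phenotypes:
  - name: cholesterol
    mean: {ND: 100.0, WD: 136.0, WD-T070: 121.0}
    sd: {ND: 12.0, WD: 12.0, WD-T070: 12.0}
couplings: []
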