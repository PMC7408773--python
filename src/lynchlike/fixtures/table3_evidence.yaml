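# Multifactorial-likelihood evidence for the three MSH6 variants assessed
# in the cohort.  Decimal commas in the published table are normalized to
# decimal points; the original strings are retained in "printed" fields for
# traceability.  Per-tumor LRs and segregation LRs are inputs here (their
# calibration sources and source pedigrees are external); the pipeline
# recomputes priors used, tumor LR products, odds and posteriors from them.
# The "bayes" column of the source table is recorded but enters no product.
variants:
  - variant_id: "MSH6 c.1153_1155del p.(Arg385del)"
    category: in_frame_indel
    prior_raw: 0.134
    prior_raw_printed: "0,134"
    prior_used_printed: "0,5"
    bayes_recorded: 2.15
    segregation_lrs: [15.22]
    segregation_printed: "15,22"
    tumors:
      - {patient: "67", proband: true, index: true, cancer: CRC, age: 53,
         msi_ihc: "MSI-H & MSH6 loss", lr: null}
      - {patient: "AF1_III4", proband: true, index: true, cancer: EC, age: 59,
         msi_ihc: "MSH6 loss", lr: 7.08, printed: "7,08"}
      - {patient: "AF1_III1", proband: false, index: false, cancer: CRC, age: 59,
         msi_ihc: "MSH6 loss", lr: 4.16, printed: "4,16"}
    printed:
      tumor_lr_total: "4,16"
      odds_for_causality: "63.31"
      posterior_odds: "63.31"
      posterior_probability: "0,984"
      iarc_class: 4
  - variant_id: "MSH6 c.1618_1620del p.(Leu540del)"
    category: in_frame_indel
    prior_raw: 0.959
    prior_raw_printed: "0,959"
    prior_used_printed: "0,9"
    bayes_recorded: 1.85
    segregation_lrs: [1.85]
    segregation_printed: "1,85"
    tumors:
      - {patient: "70", proband: true, index: true, cancer: CRC, age: 46,
         msi_ihc: "MSI-H & MSH6 loss", lr: 6.54, printed: "6,54"}
      - {patient: "70", proband: true, index: false, cancer: CRC, age: 43,
         msi_ihc: "MSI-H & MSH6 loss", lr: 6.54, printed: "6,54"}
      - {patient: "75", proband: true, index: true, cancer: CRC, age: 45,
         msi_ihc: "MSI-H & MSH6 loss", lr: null}
    printed:
      tumor_lr_total: "6,54"
      odds_for_causality: "12,07"
      posterior_odds: "108,62"
      posterior_probability: "0,991"
      iarc_class: 5
  - variant_id: "MSH6 c.3150_3161dup p.(Val1051_Ile1054dup)"
    category: in_frame_indel
    prior_raw: 0.961
    prior_raw_printed: "0,961"
    prior_used_printed: "0,9"
    bayes_recorded: null
    segregation_lrs: [28.75]   # pooled over families AF2/AF3 (single printed value)
    segregation_printed: "28,75"
    tumors:
      - {patient: "82", proband: true, index: true, cancer: OC, age: 47,
         msi_ihc: "MSI-H & PMS2 loss", lr: null}
      - {patient: "AF2_II2", proband: true, index: true, cancer: CRC, age: 61,
         msi_ihc: "MSI-H & MSH6 loss", lr: 0.99, printed: "0,99"}
      - {patient: "AF3_III3", proband: true, index: true, cancer: CRC, age: 47,
         msi_ihc: "MSH6 loss", lr: 29.08, printed: "29,08"}
      - {patient: "AF3_II2", proband: false, index: false, cancer: EC, age: 56,
         msi_ihc: "MSH6 loss", lr: 1.75, printed: "1,75"}
      - {patient: "AF3_II2", proband: false, index: false, cancer: CRC, age: 75,
         msi_ihc: "MSI-H & MSH6 loss", lr: 4.16, printed: "4,16"}
      - {patient: "AF3_II11", proband: false, index: false, cancer: CRC, age: 68,
         msi_ihc: "MSI-H", lr: 4.16, printed: "4,16"}
    printed:
      tumor_lr_total: "30,28"
      odds_for_causality: "870,61"
      posterior_odds: "7835,47"
      posterior_probability: "1,000"
      iarc_class: 5
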