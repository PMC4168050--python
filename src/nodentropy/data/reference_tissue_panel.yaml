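# Reference 10-tissue panel for the entropy analysis (19 experiments).
# Nodule pools four post-inoculation stages, seed pools six
# days-after-pollination stages, root pools the nodulation 0 dpi control
# and an independent root experiment; the remaining seven tissues are
# single experiments.
- tissue: leaf
  conditions: [leaf]
- tissue: petiole
  conditions: [petiole]
- tissue: stem
  conditions: [stem]
- tissue: bud
  conditions: [vegetative_bud]
- tissue: flower
  conditions: [flower]
- tissue: seed
  conditions:
    - seed_10dap
    - seed_12dap
    - seed_16dap
    - seed_20dap
    - seed_24dap
    - seed_36dap
- tissue: pod
  conditions: [seed_pod]
- tissue: root
  conditions:
    - root_0dpi_control
    - root_independent
- tissue: nodule
  conditions:
    - nodule_4dpi
    - nodule_10dpi
    - nodule_14dpi
    - nodule_28dpi
- tissue: mycorrhiza
  conditions: [mycorrhizal_root]
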