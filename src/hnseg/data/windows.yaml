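# HU window presets per organ category.
# Soft-tissue organs use [-140, 210] HU; skeletal structures [-350, 1250] HU.
windows:
  soft_tissue:
    lower: -140
    upper: 210
  skeletal:
    lower: -350
    upper: 1250
organs:
  brain_stem: soft_tissue
  parotid: soft_tissue
  esophagus: soft_tissue
  optic_nerve: soft_tissue
  optic_chiasm: soft_tissue
  pharyngeal_constrictor: soft_tissue
  mandible: skeletal
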