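# Ligand blacklist for drug-target dataset construction.
#
# A ligand is excluded when it has `max_heavy_atoms` or fewer non-hydrogen
# atoms, or its PDB chemical component id appears below.  The component list
# covers common crystallization additives, buffer components, detergents,
# solutes and ubiquitous cofactors; it is intentionally editable — extend it
# to match the stringency of your own dataset.
max_heavy_atoms: 5

excluded_comp_ids:
  # cryoprotectants / precipitants / buffer components
  - GOL   # glycerol
  - EDO   # ethylene glycol
  - PEG   # di(hydroxyethyl)ether
  - PGE   # triethylene glycol
  - P6G   # hexaethylene glycol
  - MPD   # 2-methyl-2,4-pentanediol
  - TRS   # tris buffer
  - EPE   # HEPES
  - MES   # MES buffer
  - CIT   # citrate
  - FLC   # citrate anion
  - TAR   # tartaric acid
  - MLI   # malonate
  # detergents
  - BOG   # octyl beta-D-glucopyranoside
  - LDA   # lauryl dimethylamine-N-oxide
  - SDS   # sodium dodecyl sulfate (detergent form)
  - BNG   # nonyl glucoside
  - C8E   # octyl PEG ether
  # reducing agents / additives
  - BME   # beta-mercaptoethanol
  - DTT   # dithiothreitol
  - MRD   # (4R)-2-methylpentane-2,4-diol
  # ubiquitous cofactors and carriers
  - NAD
  - NAI
  - NAP
  - NDP
  - FAD
  - FMN
  - ATP
  - ADP
  - AMP
  - ANP
  - GTP
  - GDP
  - COA
  - ACO
  - HEM
  - HEC
  - SAM
  - PLP
  - TPP
  - BTN   # biotin
  # common sugars from glycosylation
  - NAG
  - NDG
  - BMA
  - MAN
  - GAL
  - GLC
  - FUC
  - SIA
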