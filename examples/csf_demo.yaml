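# Sham vs 7-day-injury demo: injury-induced CSF pathway (Csf1 from lining
# fibroblasts, Il34 from pericytes, receptor Csf1r on macrophages) planted
# among 20 decoy pathways.
out: runs/csf_demo
seed: 7
pipeline:
  n_perm: 100
  alpha: 0.05
  min_cells: 10
  kh: 0.5
simulate:
  conditions: [Sham, ACLR7]
  clusters:
    - {name: FibroLining, compartment: stromal, cells: 150}
    - {name: Pericyte, compartment: stromal, cells: 100}
    - {name: Macrophage, compartment: immune, cells: 150}
    - {name: TCell, compartment: immune, cells: 100}
  n_genes: 2000
  nb_mean: 0.5
  nb_dispersion: 2.0
  n_decoys: 20
  planted:
    - pathway: CSF
      ligand: Csf1
      receptor: Csf1r
      sender: FibroLining
      receiver: Macrophage
      active: [ACLR7]
      fold_effect: 8
      exclusive: true
    - pathway: CSF
      ligand: Il34
      receptor: Csf1r
      sender: Pericyte
      receiver: Macrophage
      active: [ACLR7]
      fold_effect: 6
      exclusive: true
de:
  comparisons:
    - name: mac
      group: {cluster: Macrophage, condition: ACLR7}
      versus: {cluster: Macrophage, condition: Sham}
    - name: tcell
      group: {cluster: TCell, condition: ACLR7}
      versus: {cluster: TCell, condition: Sham}
  overlap: [mac, tcell]
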