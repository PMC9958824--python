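# Physiological ion table for mammalian brain tissue: monovalent ion
# concentrations on either side of the neuronal membrane, with the
# impermeant anions (A-, charged metabolites and macromolecules) present in
# both compartments.  Extracellular space takes a quarter of the tissue
# volume; both sides total 304 mM (isotonic) and carry zero net charge.
alpha: 0.25
temperature: 310.0
ions:
  - {name: "Na+", valence: 1, permeant: true, conc_out: 148.0, conc_in: 12.0}
  - {name: "K+", valence: 1, permeant: true, conc_out: 4.0, conc_in: 140.0}
  - {name: "Cl-", valence: -1, permeant: true, conc_out: 113.0, conc_in: 8.0}
  - {name: "HCO3-", valence: -1, permeant: true, conc_out: 29.0, conc_in: 10.0}
  - {name: "A-", valence: -1, permeant: false, conc_out: 10.0, conc_in: 134.0}
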