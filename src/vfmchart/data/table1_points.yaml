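
# Illustrative points system for the incremental-benefits variable of the
# value-for-money framework.  Point values were elicited from a convenience
# sample by pairwise ranking and are illustrative, not normative.
name: Illustrative incremental-benefits points system
metadata:
  provenance: illustrative schedule elicited from a convenience sample by pairwise ranking
  cost_convention: annual
dimensions:
  - name: Lives saved
    levels:
      - label: "None (or not yet known)"
        points: 0
      - label: "Few: 1-50 lives saved"
        points: 0.091
      - label: "Some: 51-250 lives saved"
        points: 0.192
      - label: "Many: 251-500 lives saved"
        points: 0.268
      - label: "Very many: >500 lives saved"
        points: 0.343
  - name: Life-prolongation benefits
    levels:
      - label: "None/Very small (or not yet known)"
        points: 0
      - label: "Small benefits"
        points: 0.053
      - label: "Medium benefits"
        points: 0.152
      - label: "Large benefits"
        points: 0.244
  - name: Quality-of-life (QoL) gains
    levels:
      - label: "None/Very small (or not yet known)"
        points: 0
      - label: "Small QoL gains"
        points: 0.051
      - label: "Medium QoL gains"
        points: 0.138
      - label: "Large QoL gains"
        points: 0.217
  - name: If this technology were not to be funded
    levels:
      - label: "Many/most patients will be able to pay for it themselves (privately)"
        points: 0
      - label: "Many/most patients will get an alternative treatment (less effective) already funded by government"
        points: 0.055
      - label: "Many/most patients will not receive any treatment for condition"
        points: 0.108
  - name: Other important social or ethical benefits
    levels:
      - label: "None/Very small (or not yet known)"
        points: 0
      - label: "Yes"
        points: 0.087
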