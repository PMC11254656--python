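# Default assignment of the 11 immunotherapy cohorts to five treatment-class
# groups. The PD-L1 group (PD-L1 inhibitor + chemotherapy) is the control.
control_group: PD-L1
groups:
  - name: PD-L1
    role: control
    members:
      - impower133_atezo
      - caspian_durva
      - capstone1_adebrelimab
      - skyscraper02_atezo
  - name: PD-1
    role: experimental
    members:
      - keynote604_pembro
      - rationale312_tisle
      - astrum005_serplu
      - extentorch_toripa
  - name: tremelimumab
    role: experimental
    members:
      - caspian_durva_treme
  - name: tiragolumab
    role: experimental
    members:
      - skyscraper02_tira
  - name: anlotinib
    role: experimental
    members:
      - eter701_benmel_anlo
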