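# DISABKIDS chronic-generic (DCGM-37) and diabetes-specific (DSM-10)
# subscale structure: eight subscales over four domains, five ordered
# response categories per item.  Orientation "positive" codes never=0 ..
# always=4; "negative" codes never=4 .. always=0, so a high coded score
# always means few problems.
scales:
  - name: independence
    domain: mental
    items: [CG1, CG2, CG3, CG4, CG5, CG6]
    orientation: positive
  - name: emotion
    domain: mental
    items: [CG13, CG14, CG15, CG16, CG17, CG18, CG19]
    orientation: negative
  - name: inclusion
    domain: social
    items: [CG26, CG27, CG28, CG29, CG30, CG31]
    orientation: positive
  - name: exclusion
    domain: social
    items: [CG20, CG21, CG22, CG23, CG24, CG25]
    orientation: negative
  - name: limitation
    domain: physical
    items: [CG7, CG8, CG9, CG10, CG11, CG12]
    orientation:
      CG7: positive
      CG8: negative
      CG9: negative
      CG10: negative
      CG11: negative
      CG12: negative
  - name: treatment
    domain: physical
    items: [CG32, CG33, CG34, CG35, CG36, CG37]
    orientation: negative
  - name: impact
    domain: diabetes
    items: [DM1, DM2, DM3, DM4, DM5, DM6]
    orientation: negative
  - name: dm_treatment
    domain: diabetes
    items: [DM7, DM8, DM9, DM10]
    orientation: negative

# subscale pairs compared for joint unidimensionality, one per domain with
# two generic subscales
unidimensionality_pairs:
  - [independence, emotion]
  - [inclusion, exclusion]
  - [limitation, treatment]
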