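params:
  k: 1.0
  g0: 50.0
  lambda_a: 8.0
  lambda_r: 0.5
  h_a: 2.0
  h_r: 1.875
  omega: 1000.0
  volume: 50.0
nodes:
- name: P53
  kind: protein
  g0: 50.0
  k: 1.0
- name: MDM2
  kind: protein
  g0: 50.0
  k: 1.0
- name: ZEB
  kind: protein
  g0: 50.0
  k: 1.0
- name: OCT4
  kind: protein
  g0: 50.0
  k: 1.0
- name: miR145
  kind: microRNA
  g0: 50.0
  k: 1.0
- name: miR200
  kind: microRNA
  g0: 50.0
  k: 1.0
regulations:
- source: miR200
  target: ZEB
  sign: repression
  m: 2
- source: P53
  target: miR200
  sign: activation
  m: 4
- source: P53
  target: miR145
  sign: activation
  m: 4
- source: P53
  target: MDM2
  sign: activation
  m: 4
- source: miR145
  target: ZEB
  sign: repression
  m: 2
- source: miR145
  target: OCT4
  sign: repression
  m: 2
- source: miR145
  target: MDM2
  sign: repression
  m: 2
- source: ZEB
  target: miR200
  sign: repression
  m: 4
- source: ZEB
  target: miR145
  sign: repression
  m: 4
- source: ZEB
  target: ZEB
  sign: activation
  m: 4
- source: OCT4
  target: miR200
  sign: activation
  m: 4
- source: OCT4
  target: miR145
  sign: repression
  m: 2
- source: MDM2
  target: P53
  sign: repression
  m: 4
- source: OCT4
  target: OCT4
  sign: activation
  m: 4
- source: P53
  target: P53
  sign: activation
  m: 4
- source: P53
  target: OCT4
  sign: repression
  m: 2
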