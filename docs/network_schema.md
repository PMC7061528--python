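# Network config schema

A network file is a YAML document with three top-level keys.

## `params`

Global kinetic parameters (all optional; defaults shown):

| key        | default | meaning |
|------------|---------|---------|
| `k`        | 1.0     | degradation rate (1/time) |
| `g0`       | 50.0    | base synthesis rate (molecules/time) |
| `lambda_a` | 8.0     | synthesis fold per bound activating site (> 1) |
| `lambda_r` | 0.5     | synthesis fold per bound repressing site (in (0, 1)) |
| `h_a`      | 2.0     | binding rate constant, activating sites |
| `h_r`      | 1.875   | binding rate constant, repressing sites |
| `omega`    | 1000.0  | adiabaticity ratio; unbinding rate f = k * omega |
| `volume`   | 1.0     | mass-action system-size constant; an order-m binding propensity carries 1/volume^(m-1) |

## `nodes`

List of species. Each entry:

```yaml
- name: P53        # unique identifier
  kind: protein    # protein | microRNA (kinetically identical)
  g0: 50.0         # optional, defaults to params.g0
  k: 1.0           # optional, defaults to params.k
```

## `regulations`

List of binding sites; each regulation defines exactly one site on its
target gene:

```yaml
- source: miR200       # regulator species
  target: ZEB          # gene carrying the site
  sign: repression     # activation | repression
  m: 2                 # multimer order: 1, 2 or 4
  h: 2.0               # optional per-site binding rate override
  f: 1000.0            # optional per-site unbinding rate override
  lam: 0.5             # optional per-site synthesis fold override
  strength_scale: 1.0  # multiplier on h (used by sensitivity scans)
```

Binding propensities (free source copies n, rate h' = h * strength_scale /
volume^(m-1)):

    m = 1:  h' * n
    m = 2:  h' * n(n-1)/2
    m = 4:  h' * n(n-1)(n-2)(n-3)/6

Binding sequesters `m` copies of the source species until unbinding.
Validate a file with `grn-landscape network validate <file>`.

The shipped default (`src/grn_landscape/data/default_network.yaml`) is the
6-node circuit with 16 regulations (7 activations, 9 repressions) and
`volume: 50`.
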