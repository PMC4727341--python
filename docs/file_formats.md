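# File formats

## Influence-diagram JSON (`to_json` / `from_json`, `generate-id`)

```json
{
  "variables": [{"name": "X", "role": "chance|decision|utility",
                 "states": ["s0", "s1"] }],
  "decision_order": ["D0", "D1"],
  "observations": {"D0": [], "D1": ["X"]},
  "cpts": [{"child": "X", "parents": ["D0"], "values": [/* flat */]}],
  "utilities": [{"node": "U0", "parents": ["X"], "values": [/* flat */]}],
  "supervalues": [{"node": "U", "operator": "sum|product",
                   "terms": [["U0", 1], ["U1", -1]]}],
  "root_value": "U"
}
```

Utility variables carry `"states": null`. Tables are flattened row-major:
parent axes in declared order (the child's state axis last for CPTs), the
last axis varying fastest — the same convention used for policy tables
and configuration enumeration everywhere in the package. The writer is
deterministic and the reader/writer pair round-trips bit-exactly.

## Parameter configuration YAML

A list of records, one per independent parameter:

```yaml
- id: sens_ct                 # identifier used throughout the API/CLI
  description: CT scan sensitivity
  mean: 0.55                  # reference value, natural scale
  units: probability          # probability | QALY | EUR | EUR/QALY
  source_table: baseline      # grouping label
  interval: [0.332, 0.758]    # published interval; default threshold scan range
  second_order: {method: mean_cv, k: 0.2}
```

`second_order.method` is one of `counts` (inputs `m`, `n`), `mean_cv`
(`k`), `mean_ci95` / `mean_range999` (`lower`, `upper`), `uniform`
(`lower`, `upper`), `gamma` (`k`), `degenerate`. Fits are recomputed from
these raw inputs at load time; fitted shape parameters are never stored.
The shipped reference file is
`src/mediastage/data/reference_parameters.yaml`.

## Strategy-tree formats (`render`)

* `text` — two-space indentation per level; action lines `Dec = option`,
  branch lines `[var=state, ...]`, merged branches separated by `|`.
* `dot` — Graphviz digraph; actions as boxes, observations as ellipses
  with outcome-labelled edges; deterministic node numbering.
* `json` — nested `{"type": "action"|"observation", ...}` objects;
  `parse_json` round-trips exactly.

## CLI reports

`mediastage evaluate` writes `report.json` (MEU, criterion, λ, λ⁻¹,
SHA-256 of the parameter values, package version), `policies.json`
(per decision, the consistent configurations and the chosen option), and
the strategy tree in all three formats. `mediastage sensitivity` writes
`<analysis>.csv` (one row per parameter, or per parameter with one
`p_change[decision]` column per decision) plus `<analysis>.json` with a
`meta` block (analysis, criterion, seed, samples, grid step, parameter
hash, version) and the same rows.
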