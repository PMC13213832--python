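# Screening JSON dialect

`to_screening_json` emits a points document in the screening engine's
(Pharmer-convention) dialect; `model_from_json` parses it back losslessly
(coordinates to the emitted 3-decimal precision). A golden example lives at
`tests/data/golden_model.json`.

```
{"points": [ <point>, ... ]}
```

Each feature point:

| key | type | meaning |
|---|---|---|
| `name` | string | `HydrogenDonor`, `HydrogenAcceptor`, `Hydrophobic`, `Aromatic`, `PositiveIon`, `NegativeIon` |
| `x`,`y`,`z` | number | position, Å, 3 decimals |
| `radius` | number | feature radius, Å |
| `enabled` | bool | always `true` on export |
| `vector` | list of `{x,y,z}` | unit directions — 1 for H-bond features (donor→acceptor), 2 opposite ring normals for aromatic; absent otherwise |
| `vector_on` | int | 1 when directions are present |
| `partner` | string | contributing chain id (extension key) |
| `raw_score`, `normalized_score` | number | scoring metadata (extension keys) |
| `residue_index`, `atom_index` | int | provenance (extension keys) |

Exclusion spheres follow the features, one per protein heavy atom:

```
{"name": "ExclusionSphere", "x": ..., "y": ..., "z": ..., "radius": 1.0, "enabled": true}
```

Keys are emitted sorted, so documents diff cleanly. Consumers that only
understand the engine's core keys can ignore the extension keys.
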