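# JSON model dialect

A minimal, COBRA-compatible JSON layout for metabolic network models, read
and written by `metactivity.model_io.read_model` / `write_model`.

## Top-level object

| key           | type   | notes                                        |
|---------------|--------|----------------------------------------------|
| `name`        | string | optional free text                           |
| `version`     | string | optional free text                           |
| `metabolites` | array  | one object per metabolite                    |
| `reactions`   | array  | one object per reaction                      |
| `genes`       | array  | gene identifier strings; if omitted, the set is inferred from the GPR rules |

## Metabolite object

| key           | type   | notes                       |
|---------------|--------|-----------------------------|
| `id`          | string | unique within the model     |
| `name`        | string | optional                    |
| `compartment` | string | compartment tag, e.g. `c`, `m`, `r` |

## Reaction object

| key                  | type   | notes                                              |
|----------------------|--------|----------------------------------------------------|
| `id`                 | string | unique within the model                            |
| `name`               | string | optional                                           |
| `metabolites`        | object | metabolite id → stoichiometric coefficient (negative = consumed) |
| `lower_bound`        | number | flux units; if omitted, defaults to −1000 with a logged warning |
| `upper_bound`        | number | flux units; if omitted, defaults to 1000 with a logged warning |
| `gene_reaction_rule` | string | infix boolean rule: gene tokens, `and` / `or` (case-insensitive), parentheses; `and` binds tighter than `or`; empty string = no gene association |
| `subsystem`          | string | optional pathway label                             |

## Validation

On load the model is checked for: unique ids per namespace; stoichiometries
referencing only declared metabolites; GPR rules referencing only declared
genes (when `genes` is present); `lower_bound <= upper_bound`. Violations
raise `ModelLoadError`.

## Example

```json
{
 "name": "chain",
 "metabolites": [{"id": "A", "compartment": "c"},
                 {"id": "B", "compartment": "c"}],
 "reactions": [
  {"id": "EX_in", "metabolites": {"A": 1.0},
   "lower_bound": 0.0, "upper_bound": 10.0, "gene_reaction_rule": ""},
  {"id": "r_ab", "metabolites": {"A": -1.0, "B": 1.0},
   "lower_bound": 0.0, "upper_bound": 10.0,
   "gene_reaction_rule": "g1 and (g2 or g3)"},
  {"id": "EX_out", "metabolites": {"B": -1.0},
   "lower_bound": 0.0, "upper_bound": 10.0, "gene_reaction_rule": ""}
 ],
 "genes": ["g1", "g2", "g3"]
}
```
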