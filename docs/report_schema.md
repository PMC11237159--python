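# Analysis report JSON schema (version 1)

`glue-evo run` and `glueevo.pipeline.run_pipeline` emit a single JSON object.
All keys are sorted; the only non-deterministic field for a fixed config and
seed is `timestamp`.

```
{
  "schema_version": "1",
  "tool": {"name": "glue-evo", "version": "<semver>"},
  "seed": <int>,                      # master seed used by stochastic stages
  "timestamp": "<ISO-8601 UTC>",
  "inputs": {"<path>": "<sha256>"},   # every input file consumed
  "stages": {
    "expression":   {"status": "run" | "skipped", ...},
    "architecture": {...},
    "properties":   {...},
    "selection":    {...},
    "pulltest":     {...}
  }
}
```

Each executed stage carries `"params"` (non-file config values) and
`"results"`:

- **expression** — `focal_species`, `pseudocount`, `null_size`, and
  `ratios`: a list of `{gene, ratio, p}` where `ratio` is
  TPM_glue / max non-glue TPM and `p` the add-one empirical p-value.
- **architecture** — per sequence id: `repeats` (list of
  `{start, end, unit_length, copy_number, consensus, mean_identity,
  unit_pg_counts, unit_st_counts}`), `segments` (ordered
  `{start, end, kind, label}`), and, when a glyco track was supplied,
  `glyco_candidates_per_region`.
- **properties** — per sequence id: list of domain profiles
  (`label`, span, `length`, `gravy`, `pct_disorder`, `pct_helix`,
  `pct_beta`, `pct_coil`, `composition`, `n_unknown`, `mw`, `pi`; metrics
  without the needed track are null).
- **selection** — `positive_sites`
  (`{label, n_sites, n_positive, percent_positive, posterior_threshold}`)
  when a site-class table was supplied; `ng86` (`pairs` of
  `{a, b, dN, dS, omega, n_skipped}` plus `mean_omega`) when a codon
  alignment was supplied. Undefined distances (saturation, dS = 0) are null.
- **pulltest** — `groups`: per-treatment `{treatment, n, mean, sd}` in kPa
  (`sd` null for singletons); `comparison`:
  `{treatment_a, treatment_b, p}` from the stratified permutation test.

Spans and positions are 1-based and inclusive throughout.
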