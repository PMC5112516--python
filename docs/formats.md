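# File formats

All text files are UTF-8, comma-separated with '.' decimals; metadata
lines start with `#` and hold `key=value` pairs. Concentrations in files
are SI molar; µM appears only in human-readable reports.

## Titration CSV (`read_titration_csv` / `write_titration_csv`)

```
# p_total=5.5e-06          (required; total protein, M)
# f_init=1000.0            (or provide a dna_total=0 row)
# buffer=PBS               (optional)
# temperature_c=25.0       (optional)
# label=Sac7d              (optional)
dna_total,fluorescence
0.0,1000.0
1.76e-06,978.2
...
```

* `dna_total` — total added DNA, M of nucleotides, strictly increasing
  after sorting; duplicates are an error. With `units="A260"` the column
  holds absorbance at 260 nm, converted as c = A260 / 6600 (1 cm path).
* `fluorescence` — arbitrary units. A `dna_total=0` row defines F_i (and
  must agree with the `f_init` metadata when both are present).

## FASTA (`read_fasta` / `write_fasta`)

Headers are `name|accession` (accession optional); sequences wrapped at
60 columns; alphabet restricted to the 20 standard residues, with `-`
allowed only in `aligned=True` mode. `family_validation=True` warns on
ungapped lengths outside 60–66 residues.

## Melting-temperature CSV (`read_tm_table`)

Columns `name, tm_c` plus optional `aggregates` (bool) and `tm_group`
(`high` / `low` / `unassigned`). The packaged `data/study_table.csv` is a
superset of this layout with the binding and mass columns added
(`mw_measured_da, mw_tagged_calc_da, yield_mg_per_l, kd_um, kd_err_um,
n_bases, n_err_bases`).

## JSON outputs

* Fit result: `kd_uM, kd_se_uM, n_bases, n_se, q_max, q_max_se, rss,
  n_points, converged, n_starts_tried`.
* Recovery summary: per parameter (`kd, n, q_max`) the keys
  `median_abs_rel_err, iqr_abs_rel_err, mean_signed_rel_err`, plus
  `n_replicates, n_failed`.
* `RunConfig` serialises losslessly to/from JSON.

## TSV reports

Pairwise identity/similarity matrices have protein names on both axes,
percentages at one decimal. The study-table-style fit report prints
`K_D` at integer µM and `n` at one decimal, mirroring the reporting
precision of the packaged table.
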