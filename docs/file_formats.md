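# File formats

All tables are CSV: comma-separated, UTF-8, header required, `.` decimal.
Floats are written with `repr` precision and re-read losslessly
(`float_precision="round_trip"`).

## Spectra

* **Two-column text** (`.txt`): `m/z<TAB>intensity`, one point per line,
  profile mode, `#` comments allowed. Centroided stick data is accepted and
  should be flagged by the caller in metadata.
* **mzML** (`.mzML`): profile spectra, 64-bit little-endian uncompressed
  arrays on write; 32/64-bit and zlib-compressed payloads on read. The well
  id travels as the spectrum-title CV param.

Readers retain points outside *m/z* 2000–20,000 but count them in
`metadata["out_of_range_points"]`; non-monotone axes are rejected.

## Plate map (`read_plate_map` / `write_plate_map`)

| column | type | notes |
| --- | --- | --- |
| plate | str | one plate per biological replicate (e.g. `BR1`) |
| well | str | unique within plate |
| role | enum | `test`, `positive_control`, `negative_control`, `vehicle`, `stimulated`; aliases like `pos_ctrl` are normalized |
| compound | str or empty | empty for control wells (enforced) |
| concentration | float or empty | molar for screens, µM for dose series; ≥ 0 |
| set | str | staggered compound set (`S1`…) |
| technical_replicate | int | 1-based |
| biological_replicate | int | 1-based |

Duplicate (plate, well, technical_replicate, biological_replicate) keys are
rejected. `check_plate_controls` refuses maps in which any (plate, set)
lacks a positive or negative control.

## Feature table (`write_feature_table` / `read_feature_table`)

One row per spectrum (or per well after technical aggregation): the plate
map columns plus `area_4632`, `area_4964`, `area_6891`, `raw_ratio`,
`normalized_ratio`, `percent_effect`, `flags`. NaN percent effect (control
wells) serializes as an empty field; `flags` is empty or
`zero_denominator`.

## TPP tables

Long format: `protein, condition, replicate, temperature, rel_abundance`
(abundance relative to the lowest temperature). ITDR series:
`concentration, replicate, soluble_fraction` (concentration in µM).

## Simulation configs

Any `*SimConfig` round-trips through YAML via `config_to_yaml` /
`config_from_yaml`; the file records the type tag, every field including
the seed, and nested peak/protein specs.
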