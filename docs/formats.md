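# File formats

All tabular files are UTF-8, tab-separated, with a mandatory header row;
lines starting with `#` are comments (writers put metadata such as
`# seed=...` there). Unknown columns are preserved. Concentrations are μM,
delays ms at interfaces (seconds internally), fields MHz, shifts ppm,
rates s⁻¹. Coordinates are 1-based inclusive.

| kind        | required columns                                              |
|-------------|---------------------------------------------------------------|
| shifts      | residue_index, residue_type, nucleus, shift_ppm [, ambiguous, status] |
| decay       | residue_index, delay_ms, intensity, field_mhz, rate_kind       |
| noe         | residue_index, i_sat, i_ref, field_mhz                         |
| titration   | point_id, L_uM, Tf_uM, group, observable [, observable_se]     |
| intensity   | residue_index, intensity [, intensity_se]                      |
| r0          | group, r0                                                      |

Chemical shifts are also read from NMR-STAR v3 documents containing an
`_Atom_chem_shift` loop (`io.read_shift_star`); backbone nuclei
CA/CB/C/N/H/HA are extracted, everything else ignored. `io.write_shift_star`
emits a minimal round-trippable document.

Run configuration (`fuzzfit run --config`) is YAML or JSON with the fields
of `io.RunConfig`; the pipeline summary (`summary.json`) embeds the config,
its hash and the seed.

Construct registry rows (packaged `data/constructs.tsv`) use
`label:start-end[@ref_start]` region syntax, semicolon-separated.
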