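# File formats

All reflection data are plain text (inspectable, diffable). HDF5 is
used only for image stacks, CCP4 only for maps.

## Reflection tables

Written by `sfxkit.io.write_reflection_table`, read by
`read_reflection_table`. Grammar (EBNF; `FLOAT`/`INT` are the usual
decimal literals, `WS` is any run of spaces):

```
table       = header , columns-line , { data-row } ;
header      = format-line , kind-line , cell-line , sg-line ,
              res-line , friedel-line , { extra-line } ;
format-line = "# format: sfxkit-reflections 1" , EOL ;
kind-line   = "# kind: " , ( "merged" | "structure_factors" ) , EOL ;
cell-line   = "# cell: " , FLOAT*6 , EOL ;               (* a b c alpha beta gamma *)
sg-line     = "# spacegroup: " , SYMBOL , EOL ;          (* e.g. C2, P42_12 *)
res-line    = "# resolution: " , FLOAT , WS , FLOAT , EOL ;  (* d_max d_min *)
friedel-line= "# friedel: " , ( "merged" | "separate" ) , EOL ;
extra-line  = "# " , KEY , ": " , VALUE , EOL ;          (* provenance, kept *)
columns-line= "# columns: " , NAME , { WS , NAME } , EOL ;
data-row    = VALUE , { WS , VALUE } , EOL ;
```

Columns are matched **by name**, in any order; unknown columns are
preserved. Floats are written at 6 significant figures; missing values
as `nan`.

* `kind: merged` requires columns
  `h k l d I sigma n I_A n_A I_B n_B free` (free is 0/1).
* `kind: structure_factors` requires `h k l amplitude phase_deg`.

## Stream files (per-pattern observations)

One block per still, loosely modelled on the reflection-list sections
of stream files from serial-crystallography pipelines:

```
stream   = "# format: sfxkit-stream 1" , EOL , { block } ;
block    = "BEGIN PATTERN " , INT , EOL ,
           "scale " , FLOAT , EOL ,
           "orientation " , FLOAT*9 , EOL ,       (* row-major 3x3 rotation *)
           { obs-row } ,
           "END PATTERN" , EOL ;
obs-row  = INT , WS , INT , WS , INT , WS , FLOAT , WS , FLOAT , EOL ;
           (* h k l I sigma, indices as observed, pre-ASU *)
```

## Images (HDF5)

One dataset per pattern, named `pattern_NNNNNN`, 2-D float ADU arrays;
attributes `pixel_um`, `distance_mm`, `wavelength` carry the detector
geometry.

## Maps (CCP4)

`MapGrid.write_ccp4` writes the mean-subtracted density on the full
unit-cell grid (P1 sampling, fractional origin at grid point (0,0,0))
via gemmi.

## Pipeline config (YAML)

A flat mapping; every field of `sfxkit.io.PipelineConfig` is written
explicitly (defaults included), so a run directory is self-documenting.
Unknown keys are rejected. `manifest.json` next to the outputs records
the config hash (which excludes `out_dir`), per-stage wall-clock and
output files.

## Toy structures (PDB)

Minimal PDB: `CRYST1` (cell + space group), one `ATOM`/`HETATM` record
per point atom; occupancy and B-factor columns are honoured; ligand
atoms are marked by residue name `LIG`/HETATM.
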