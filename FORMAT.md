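# File formats

## RT-boundary matrix CSV

UTF-8, comma-separated. Header:

```
precursor,charge,<run>_start,<run>_end[,<run2>_start,<run2>_end,...]
```

* `precursor` — modified peptide sequence, uppercase residues with optional
  bracketed mass offsets (e.g. `TQTHATLC[+57]STSAK`).
* `charge` — precursor charge, integer ≥ 1.
* `<run>_start` / `<run>_end` — chromatographic peak boundaries in minutes,
  written with six decimals. Every run contributes exactly one start and one
  end column; an unpaired column is a format error.
* An **empty field** (not `0`) denotes a missing value; the two members of a
  boundary pair are present or absent together.
* Run identifiers are raw-file basenames without extension.

Files may be transition-level (several rows repeating one
`precursor,charge`); on reading they are collapsed to one precursor row,
taking the per-run median when the rows agree within 0.01 min and failing
otherwise.

When a matrix carries non-trivial provenance (imputed or masked cells), a
sidecar `<name>.provenance.csv` is written next to the main file with the
same `precursor,charge` key columns and one column per run holding one of
`observed`, `imputed`, `masked`, `missing`. The reader picks the sidecar up
automatically when present.

## Spectral library (`.blib` dialect)

A single SQLite database file with the following tables (a minimal,
version-agnostic subset of the BiblioSpec layout):

| table | columns |
|---|---|
| `LibInfo` | `libLSID`, `createTime`, `numSpecs`, `majorVersion`, `minorVersion` |
| `SpectrumSourceFiles` | `id` (pk), `fileName` |
| `RefSpectra` | `id` (pk), `peptideSeq` (unmodified), `peptideModSeq`, `precursorCharge`, `precursorMZ`, `retentionTime`, `startTime`, `endTime`, `fileID` → `SpectrumSourceFiles.id` |
| `TransitionList` | `id` (pk), `peptideModSeq`, `precursorCharge`, `precursorMZ`, `productMZ`, `label` |
| `BoundaryProvenance` | `peptideModSeq`, `precursorCharge`, `fileName`, `provenance` |

Times are minutes. A record whose `startTime` or `endTime` is NULL
contributes a **missing** cell for that (precursor, source file).
`BoundaryProvenance` is auxiliary — tools unaware of it can ignore it; it
records which boundaries were imputed rather than observed. Spectrum peak
blobs are out of scope for this dialect (transition m/z values live in
`TransitionList`).

When writing with a template library, only `startTime`/`endTime` of matched
records are updated (and records are inserted for newly imputed cells); all
other fields are copied through untouched.

## Quant report TSV

Tab-separated long form, one row per (precursor, run):

```
precursor  charge  run  abundance  provenance
```

`abundance` is the background-subtracted peak area summed over the
peptide's transitions, in intensity·minutes; empty means missing.
`provenance` is `observed`, `boundary_imputed`, `plugin_imputed`, `masked`
or `missing`.

## mzML

Standard mzML 1.1 (plain or indexed). The reader requires, per spectrum:
scan start time (minute or second units), ms level, the precursor isolation
window (target m/z with lower/upper offsets) for MS2, and m/z + intensity
binary arrays (32- or 64-bit floats, zlib or uncompressed). The writer
emits plain mzML with 64-bit uncompressed arrays.

## Metadata TSVs

* Groups: `run_id<TAB>group` with groups labelled `A` and `B`.
* Dilutions: `run_id<TAB>dilution_fraction` with fractions in (0, 1]; runs
  at 1.0 are the undiluted reference.
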