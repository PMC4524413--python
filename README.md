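# lcmspipe

Modular, stepwise processing of LC-MS metabolomics data: from raw or
centroided mzML runs to an annotated, aligned cross-sample feature matrix.

Untargeted LC-MS produces, per run, thousands of (m/z, retention time,
intensity) measurements in which true metabolite signals are buried among
chemical and electronic noise, and in which one compound appears as many
related ions (protonated/deprotonated main peaks, Na⁺/K⁺ adducts,
isotopologues, in-source fragments). `lcmspipe` is for analysts and method
developers who want that reduction to be an inspectable sequence of small,
typed steps rather than a monolithic black box: every stage consumes and
produces one of three well-defined entities, and every intermediate result
can be snapshotted to disk and resumed from.

## Data model

* **Scan** `S` — a set of m/z–intensity pairs *s* at scan time *t*.
* **Feature** `F` — an ion trace: a time vector **t**, an intensity vector
  **I**, and a characteristic retention time *t*ᵣ (the apex) for a given
  m/z.
* **FeatureSet** `FS` — a set of features at an averaged *t*ᵣ, believed to
  belong to one compound because their elution profiles agree (the
  normalized inner product of the resampled intensity traces is used as
  the co-elution criterion).

## Processing stages

| stage | in → out | method |
|---|---|---|
| `read` | file → sample | mzML 1.1.0 (indexed or not; 32/64-bit, zlib or plain arrays) |
| `centroid` | sample → sample | Ricker-wavelet CWT peak picking with ridge and per-scale SNR criteria |
| `threshold`, `range` | sample → sample | intensity and m/z–rt window filters |
| `extract` | sample → features | greedy mass-trace building at ppm tolerance with gap bridging |
| `width_filter`, `exclusion`, `baseline` | features → features | scan-width gate, contaminant list, asymmetric-least-squares baseline |
| `deconvolve` | features → features | Savitzky–Golay smoothing + valley splitting, raw intensity conserved |
| `group` | features → feature sets | rt gating + elution-profile cosine, single linkage |
| `isotopes`, `adducts` | feature sets → feature sets | 1.0033548/\|z\| spacing; paired adduct rules imply a consensus neutral mass |
| `match` | feature sets → feature sets | reference library by transformed neutral mass and expected rt |

Cross-sample work (`lcmspipe.alignment`) estimates a monotone
piecewise-linear retention-time map from mutual-nearest landmark features
and builds the groups × samples feature matrix.

Workflows are small typed DAGs described in YAML; `validate` statically
rejects port-kind mismatches, cycles, unfed in-ports and bad parameters,
so a validated workflow cannot hit a type error at run time. Batch runs
handle positive- and negative-mode files automatically via per-mode
parameter variants.

## Worked example

`lcmspipe.synthetic` generates ground-truth runs (Gaussian elution peaks,
isotope envelopes, adduct series, chemical noise, m/z jitter) with a truth
manifest, so the whole chain can be exercised without any instrument data:

```python
from lcmspipe.pipeline import identification_workflow, run
from lcmspipe.synthetic import generate_standards_suite

suite = generate_standards_suite(n_pos=3, n_neg=2, n_both=1, seed=1,
                                 out_dir="scratch/standards")
wf = identification_workflow(suite.adduct_csv, suite.library_csv, min_scans=4)
report = run(wf, suite.samples)
for sid, matches in report.matches.items():
    for m in matches:
        print(f"{sid}: {m.entry.name} via {m.rule.name} "
              f"({m.mz_error_ppm:.2f} ppm)")
```

prints (7 runs: 3 positive-only, 2 negative-only, 1 compound in both modes):

```
standard_001_positive: standard_001 via M+H (0.09 ppm)
standard_001_positive: standard_001 via M+Na (0.36 ppm)
standard_002_positive: standard_002 via M+H (0.15 ppm)
standard_002_positive: standard_002 via M+Na (0.05 ppm)
standard_003_positive: standard_003 via M+H (0.70 ppm)
standard_003_positive: standard_003 via M+Na (0.57 ppm)
standard_004_negative: standard_004 via M-H (0.31 ppm)
standard_005_negative: standard_005 via M-H (0.46 ppm)
standard_006_positive: standard_006 via M+H (0.26 ppm)
standard_006_positive: standard_006 via M+Na (0.42 ppm)
standard_006_negative: standard_006 via M-H (0.04 ppm)
```

Every synthetic standard is identified through its main peak (M+H in
positive mode, M−H in negative mode) with sub-ppm mass error; the Na⁺
adducts confirm the consensus neutral mass. The same chain is available
from a shell:

```sh
lcmspipe validate workflow.yaml
lcmspipe run workflow.yaml data/*.mzML --snapshot-dir snapshots/
lcmspipe rerun workflow.yaml --from width_filter data/sample07.mzML
lcmspipe report snapshots/
```

`rerun --from` resumes mid-workflow from the stored snapshots — e.g. to
relax the scan-width filter for a sample whose main peak was too narrow,
without re-reading or re-centroiding anything.

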