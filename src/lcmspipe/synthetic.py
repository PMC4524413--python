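"""Ground-truth LC-MS sample generator.

Emulates reference-standard runs: each compound elutes as a Gaussian
chromatographic peak and appears, per adduct rule, as a monoisotopic ion
plus an isotopologue envelope.  Chemical noise (exponential-tailed, at
uniform random m/z, Poisson count per scan), a linear baseline, and
Gaussian m/z jitter can be layered on top.  Output is a minimal valid
mzML 1.1.0 file (uncompressed 64-bit arrays, spectrum-level polarity and
representation terms) plus a truth manifest CSV recording every injected
ion trace, sufficient to score recall and precision of every processing
stage without any external data.

Peak shapes are synthetic simplifications of real LC-MS data: symmetric
Gaussian elution (no tailing by default), Gaussian instrument profile in
profile mode, and a crude carbon-count isotope heuristic — not a chemical
isotope-pattern model.
"""

from __future__ import annotations

import base64
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import (
    ISOTOPE_SPACING,
    PROTON_MASS,
    POTASSIUM_CATION_MASS,
    SODIUM_CATION_MASS,
)
from .io import AdductRule
from .model import IonMode

__all__ = [
    "CompoundSpec",
    "NoiseSpec",
    "DEFAULT_ADDUCTS",
    "default_isotope_ratios",
    "generate_sample",
    "generate_standards_suite",
    "write_adduct_csv",
]

#: built-in adduct rules the generator can emit, by name
DEFAULT_ADDUCTS: dict[str, AdductRule] = {
    "M+H": AdductRule("M+H", PROTON_MASS, 1, 1),
    "M+Na": AdductRule("M+Na", SODIUM_CATION_MASS, 1, 1),
    "M+K": AdductRule("M+K", POTASSIUM_CATION_MASS, 1, 1),
    "M+2H": AdductRule("M+2H", 2 * PROTON_MASS, 2, 1),
    "2M+H": AdductRule("2M+H", PROTON_MASS, 1, 2),
    "M-H": AdductRule("M-H", -PROTON_MASS, -1, 1),
    "M+Cl": AdductRule("M+Cl", 34.969402, -1, 1),
}


def default_isotope_ratios(neutral_mass: float) -> tuple[float, float]:
    """Crude carbon-count heuristic for M+1 and M+2 relative abundances.

    Assumes ~one carbon per 14 Da and 1.1% 13C abundance; synthetic, not
    chemically exact.
    """
    n_carbon = max(1, round(neutral_mass / 14.0))
    m1 = min(1.0, 0.011 * n_carbon)
    m2 = min(1.0, m1 * m1 / 2.0)
    return (m1, m2)


@dataclass(frozen=True)
class CompoundSpec:
    """One injected compound: where and how strongly it elutes, and which
    ion species it produces."""

    name: str
    neutral_mass: float
    rt: float
    peak_sigma: float
    apex_intensity: float
    adducts: tuple[str, ...] = ("M+H",)
    isotope_ratios: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.peak_sigma > 0:
            raise ValueError("peak_sigma must be positive")
        if any(not 0 <= r <= 1 for r in self.isotope_ratios):
            raise ValueError("isotope ratios must be in [0, 1]")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: chemical noise density (peaks/scan), exponential
    intensity scale (counts), linear baseline drift (counts/s), Gaussian
    m/z jitter (ppm), per-compound rt jitter (s), and the RNG seed."""

    chemical_noise_density: float = 0.0
    noise_intensity_scale: float = 0.0
    baseline_drift: float = 0.0
    mz_jitter_ppm: float = 0.0
    rt_jitter_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("chemical_noise_density", "noise_intensity_scale",
                     "baseline_drift", "mz_jitter_ppm", "rt_jitter_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# minimal mzML 1.1.0 writing

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0" id="{sample_id}">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="{sample_id}">
    <spectrumList count="{n_spectra}" defaultDataProcessingRef="dp">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""

_POLARITY_TERM = {
    IonMode.POSITIVE: '<cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>',
    IonMode.NEGATIVE: '<cvParam cvRef="MS" accession="MS:1000129" name="negative scan" value=""/>',
    IonMode.UNKNOWN: "",
}


def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack("<%dd" % len(values), *values)
    return base64.b64encode(raw).decode("ascii")


def _binary_array_xml(values: np.ndarray, is_mz: bool) -> str:
    encoded = _encode_array(np.asarray(values, dtype=float))
    if is_mz:
        kind = ('<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" '
                'unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>')
    else:
        kind = ('<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" '
                'unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>')
    return (
        f'          <binaryDataArray encodedLength="{len(encoded)}">\n'
        '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
        '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
        f"            {kind}\n"
        f"            <binary>{encoded}</binary>\n"
        "          </binaryDataArray>\n"
    )


def spectrum_xml(
    index: int,
    rt_seconds: float,
    mz: np.ndarray,
    intensity: np.ndarray,
    mode: IonMode,
    centroided: bool | None = True,
    ms_level: int = 1,
    precursor_mz: float | None = None,
    rt_unit: str = "second",
) -> str:
    """Render one ``<spectrum>`` element (exposed for io-level tests)."""
    if rt_unit == "second":
        rt_value, unit_acc = rt_seconds, "UO:0000010"
    elif rt_unit == "minute":
        rt_value, unit_acc = rt_seconds / 60.0, "UO:0000031"
    else:
        raise ValueError("rt_unit must be 'second' or 'minute'")
    rep = ""
    if centroided is True:
        rep = '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>'
    elif centroided is False:
        rep = '<cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>'
    polarity = _POLARITY_TERM[mode]
    precursor = ""
    if ms_level > 1:
        precursor = (
            '        <precursorList count="1">\n'
            "          <precursor>\n"
            '            <selectedIonList count="1">\n'
            "              <selectedIon>\n"
            f'                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{precursor_mz!r}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
            "              </selectedIon>\n"
            "            </selectedIonList>\n"
            "          </precursor>\n"
            "        </precursorList>\n"
        )
    parts = [
        f'      <spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{len(mz)}">\n',
        f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>\n',
    ]
    if polarity:
        parts.append(f"        {polarity}\n")
    if rep:
        parts.append(f"        {rep}\n")
    parts.append(
        '        <scanList count="1">\n'
        '          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>\n'
        "          <scan>\n"
        f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt_value!r}" unitCvRef="UO" unitAccession="{unit_acc}" unitName="{rt_unit}"/>\n'
        "          </scan>\n"
        "        </scanList>\n"
    )
    if precursor:
        parts.append(precursor)
    parts.append('        <binaryDataArrayList count="2">\n')
    parts.append(_binary_array_xml(mz, is_mz=True))
    parts.append(_binary_array_xml(intensity, is_mz=False))
    parts.append("        </binaryDataArrayList>\n      </spectrum>\n")
    return "".join(parts)


def write_mzml(path: str | Path, sample_id: str, spectra_xml: Sequence[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_MZML_HEADER.format(sample_id=sample_id, n_spectra=len(spectra_xml)))
        for block in spectra_xml:
            fh.write(block)
        fh.write(_MZML_FOOTER)


# ---------------------------------------------------------------------------
# sample generation


def _iter_traces(compounds, mode, rng, rt_jitter_s):
    """Expand compounds into flat ion traces (one per adduct x isotope)."""
    traces = []
    for c in compounds:
        rt = c.rt + (rng.normal(0.0, rt_jitter_s) if rt_jitter_s > 0 else 0.0)
        for adduct_name in c.adducts:
            rule = DEFAULT_ADDUCTS[adduct_name]
            if not rule.applies_to(mode):
                continue
            mono_mz = rule.mz_for_neutral(c.neutral_mass)
            z = abs(rule.charge)
            for k, ratio in enumerate((1.0, *c.isotope_ratios)):
                traces.append({
                    "compound": c.name,
                    "adduct": adduct_name,
                    "isotope": k,
                    "mz": mono_mz + k * ISOTOPE_SPACING / z,
                    "rt": rt,
                    "sigma": c.peak_sigma,
                    "apex": c.apex_intensity * ratio,
                })
    return traces


def generate_sample(
    compounds: Sequence[CompoundSpec],
    noise: NoiseSpec,
    mode: IonMode,
    path: str | Path,
    scan_interval: float = 1.5,
    duration: float = 960.0,
    profile: bool = False,
    mz_range: tuple[float, float] = (80.0, 650.0),
    profile_spacing: float = 0.01,
    profile_sigma_points: float = 4.0,
    sample_id: str | None = None,
) -> tuple[Path, pd.DataFrame]:
    """Write one synthetic LC-MS run as mzML plus its truth manifest.

    Scans are emitted every ``scan_interval`` seconds over ``duration``.
    Each compound contributes, per listed adduct, a Gaussian elution peak
    at the rule's m/z plus isotopologue peaks spaced 1.0033548/|z|, scaled
    by its isotope ratios.  In profile mode every stick is rendered as a
    Gaussian of ``profile_sigma_points`` grid points on a uniform m/z grid
    of ``profile_spacing`` Th.  The manifest (written next to the mzML as
    ``<stem>.truth.csv``) records every injected trace's true m/z, rt,
    adduct, isotope index and apex.  Identical seeds give identical bytes.
    """
    if duration <= 0 or scan_interval <= 0:
        raise ValueError("duration and scan_interval must be positive")
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    rng = np.random.default_rng(noise.seed)
    traces = _iter_traces(compounds, mode, rng, noise.rt_jitter_s)

    scan_times = np.arange(0.0, duration, scan_interval)
    spectra = []
    for index, t in enumerate(scan_times):
        peak_mz, peak_int = [], []
        for tr in traces:
            if abs(t - tr["rt"]) > 5.0 * tr["sigma"]:
                continue
            inten = tr["apex"] * np.exp(-0.5 * ((t - tr["rt"]) / tr["sigma"]) ** 2)
            mz = tr["mz"]
            if noise.mz_jitter_ppm > 0:
                mz *= 1.0 + rng.normal(0.0, noise.mz_jitter_ppm) * 1e-6
            peak_mz.append(mz)
            peak_int.append(inten)
        if noise.chemical_noise_density > 0:
            n_noise = rng.poisson(noise.chemical_noise_density)
            for _ in range(n_noise):
                peak_mz.append(rng.uniform(*mz_range))
                peak_int.append(rng.exponential(noise.noise_intensity_scale))
        baseline = noise.baseline_drift * t
        if baseline > 0:
            peak_int = [v + baseline for v in peak_int]
        mz_arr = np.asarray(peak_mz)
        int_arr = np.asarray(peak_int)
        order = np.argsort(mz_arr, kind="stable")
        mz_arr, int_arr = mz_arr[order], int_arr[order]
        # merge coincident m/z values so scans stay strictly ascending
        if mz_arr.size > 1:
            keep_mz, keep_int = [mz_arr[0]], [int_arr[0]]
            for m, v in zip(mz_arr[1:], int_arr[1:]):
                if m - keep_mz[-1] < 1e-9:
                    keep_int[-1] += v
                else:
                    keep_mz.append(m)
                    keep_int.append(v)
            mz_arr, int_arr = np.asarray(keep_mz), np.asarray(keep_int)
        if profile:
            mz_arr, int_arr = _render_profile(
                mz_arr, int_arr, mz_range, profile_spacing, profile_sigma_points
            )
        spectra.append(
            spectrum_xml(index, float(t), mz_arr, int_arr, mode,
                         centroided=not profile)
        )

    write_mzml(path, sample_id, spectra)
    manifest = pd.DataFrame(
        [
            {
                "sample_id": sample_id,
                "compound": tr["compound"],
                "adduct": tr["adduct"],
                "isotope": tr["isotope"],
                "mz": tr["mz"],
                "rt": tr["rt"],
                "peak_sigma": tr["sigma"],
                "apex_intensity": tr["apex"],
                "ion_mode": mode.value,
            }
            for tr in traces
        ],
        columns=["sample_id", "compound", "adduct", "isotope", "mz", "rt",
                 "peak_sigma", "apex_intensity", "ion_mode"],
    )
    manifest.to_csv(path.with_suffix(".truth.csv"), index=False)
    return path, manifest


def _render_profile(mz_sticks, int_sticks, mz_range, spacing, sigma_points):
    """Render centroid sticks as Gaussians on a uniform m/z grid."""
    grid = np.arange(mz_range[0], mz_range[1] + spacing, spacing)
    out = np.zeros_like(grid)
    sigma = sigma_points * spacing
    for m, v in zip(mz_sticks, int_sticks):
        lo = np.searchsorted(grid, m - 6 * sigma)
        hi = np.searchsorted(grid, m + 6 * sigma)
        out[lo:hi] += v * np.exp(-0.5 * ((grid[lo:hi] - m) / sigma) ** 2)
    return grid, out


# ---------------------------------------------------------------------------
# reference-standards suite


def write_adduct_csv(path: str | Path, names: Sequence[str] | None = None) -> Path:
    """Write the built-in adduct rules (or a named subset) as a CSV side-input."""
    names = list(names) if names is not None else list(DEFAULT_ADDUCTS)
    lines = ["name,mass_shift,charge,multiplier"]
    for n in names:
        r = DEFAULT_ADDUCTS[n]
        lines.append(f"{r.name},{r.mass_shift!r},{r.charge},{r.multiplier}")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@dataclass(frozen=True)
class StandardsSuite:
    """Output of :func:`generate_standards_suite`."""

    samples: tuple[Path, ...]
    manifests: tuple[pd.DataFrame, ...] = field(repr=False, default=())
    library_csv: Path = Path()
    adduct_csv: Path = Path()


def _random_compound(name: str, rng: np.random.Generator) -> CompoundSpec:
    mass = float(rng.uniform(100.0, 600.0))
    return CompoundSpec(
        name=name,
        neutral_mass=mass,
        rt=float(rng.uniform(60.0, 900.0)),
        peak_sigma=float(rng.uniform(2.0, 6.0)),
        apex_intensity=float(rng.uniform(5e4, 5e5)),
        adducts=(),  # filled per mode
        isotope_ratios=default_isotope_ratios(mass),
    )


def generate_standards_suite(
    n_pos: int,
    n_neg: int,
    n_both: int,
    seed: int,
    out_dir: str | Path,
    noise: NoiseSpec | None = None,
    scan_interval: float = 1.5,
    duration: float = 960.0,
) -> StandardsSuite:
    """Generate single-compound reference-standard runs plus side inputs.

    ``n_pos`` compounds are run in positive mode only, ``n_neg`` in
    negative only, and ``n_both`` in both modes (two files each), with
    random neutral masses in [100, 600] Da and rt in [60, 900] s.  Writes
    one mzML + truth manifest per run, a combined reference-library CSV
    and an adduct-rule CSV.  Deterministic under ``seed``.
    """
    if min(n_pos, n_neg, n_both) < 0:
        raise ValueError("counts must be non-negative")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    base_noise = noise if noise is not None else NoiseSpec(
        chemical_noise_density=2.0,
        noise_intensity_scale=400.0,
        baseline_drift=0.0,
        mz_jitter_ppm=1.0,
        rt_jitter_s=0.0,
    )

    plan: list[tuple[str, CompoundSpec, IonMode]] = []
    library_rows = []
    idx = 0
    for group, count, modes in (
        ("pos", n_pos, (IonMode.POSITIVE,)),
        ("neg", n_neg, (IonMode.NEGATIVE,)),
        ("both", n_both, (IonMode.POSITIVE, IonMode.NEGATIVE)),
    ):
        for _ in range(count):
            idx += 1
            c = _random_compound(f"standard_{idx:03d}", rng)
            library_rows.append({
                "name": c.name,
                "neutral_mass": c.neutral_mass,
                "expected_rt": c.rt,
                "ion_modes": ";".join(m.value for m in modes),
            })
            for m in modes:
                plan.append((f"{c.name}_{m.value}", c, m))

    samples, manifests = [], []
    for run_id, compound, mode in plan:
        adducts = ("M+H", "M+Na") if mode is IonMode.POSITIVE else ("M-H",)
        c = CompoundSpec(
            name=compound.name,
            neutral_mass=compound.neutral_mass,
            rt=compound.rt,
            peak_sigma=compound.peak_sigma,
            apex_intensity=compound.apex_intensity,
            adducts=adducts,
            isotope_ratios=compound.isotope_ratios,
        )
        run_noise = NoiseSpec(
            chemical_noise_density=base_noise.chemical_noise_density,
            noise_intensity_scale=base_noise.noise_intensity_scale,
            baseline_drift=base_noise.baseline_drift,
            mz_jitter_ppm=base_noise.mz_jitter_ppm,
            rt_jitter_s=base_noise.rt_jitter_s,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        path, manifest = generate_sample(
            [c], run_noise, mode, out_dir / f"{run_id}.mzML",
            scan_interval=scan_interval, duration=duration,
        )
        samples.append(path)
        manifests.append(manifest)

    library_csv = out_dir / "reference_library.csv"
    pd.DataFrame(
        library_rows, columns=["name", "neutral_mass", "expected_rt", "ion_modes"]
    ).to_csv(library_csv, index=False)
    adduct_csv = write_adduct_csv(out_dir / "adducts.csv",
                                  ["M+H", "M+Na", "M-H"])
    return StandardsSuite(
        samples=tuple(samples),
        manifests=tuple(manifests),
        library_csv=library_csv,
        adduct_csv=adduct_csv,
    )
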