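"""Isotope, adduct and identity annotation of feature sets.

Within a feature set (co-eluting ions of one compound):

* isotopologue peaks sit +k * 1.0033548/|z| Th above the monoisotopic
  peak (k = 1, 2, ...; charge inferred from the spacing) with bounded
  intensity ratios;
* adduct pairs (e.g. M+H and M+Na) imply the same neutral mass under
  their respective ionisation rules, neutral(f, r) =
  (mz(f) * |charge| - mass_shift) / multiplier;
* identity matches compare a member's m/z against a reference compound's
  neutral mass transformed by a mode-applicable rule, optionally gated on
  expected retention time.

Annotation is non-destructive: features are never removed or reordered,
outputs differ from inputs only in annotations and the consensus neutral
mass.  Fragment annotation rides on the same rule machinery via
user-supplied neutral-loss rules (negative mass shifts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .constants import ISOTOPE_SPACING
from .grouping import profile_inner_product
from .io import AdductRule, ReferenceEntry
from .model import Annotation, AnnotationKind, Feature, FeatureSet, IonMode

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationParams",
    "ReferenceMatch",
    "annotate_isotopes",
    "annotate_adducts",
    "match_reference",
    "main_peak",
]


@dataclass(frozen=True)
class AnnotationParams:
    """Mass-difference tolerance (ppm), the deepest isotopologue searched,
    and the maximum allowed M+k : M apex-intensity ratio."""

    tol_ppm: float = 10.0
    max_isotopes: int = 3
    isotope_max_ratio: float = 1.1
    charges: tuple[int, ...] = (1, 2)

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")
        if self.max_isotopes < 1:
            raise ValueError("max_isotopes must be >= 1")


@dataclass(frozen=True)
class ReferenceMatch:
    """One identity candidate: a feature set matched to a library entry
    via an adduct rule, with its mass and rt errors."""

    feature_set: FeatureSet
    entry: ReferenceEntry
    rule: AdductRule
    feature_id: int
    mz_error_ppm: float
    rt_error_s: float | None


def _rebuild(fs: FeatureSet, features: Sequence[Feature],
             neutral_mass: float | None = None) -> FeatureSet:
    return FeatureSet(id=fs.id, features=tuple(features), rt=fs.rt,
                      neutral_mass=neutral_mass if neutral_mass is not None
                      else fs.neutral_mass)


def annotate_isotopes(fs: FeatureSet,
                      params: AnnotationParams = AnnotationParams()) -> FeatureSet:
    """Label isotopologue members of a feature set.

    Features are scanned in ascending m/z; each feature not itself an
    isotope anchors a chain, and any heavier member whose spacing matches
    k * 1.0033548/|z| (k up to ``max_isotopes``, z in ``charges``) within
    ``tol_ppm`` and whose apex does not exceed ``isotope_max_ratio`` times
    the anchor's gains an ISOTOPE annotation "M+k" scored by the elution
    profile inner product with the anchor.
    """
    members = sorted(fs.features, key=lambda f: f.mz)
    new_annotations: dict[int, list[Annotation]] = {f.id: [] for f in members}
    is_isotope: set[int] = set()
    for anchor in members:
        if anchor.id in is_isotope:
            continue
        for candidate in members:
            if candidate.id == anchor.id or candidate.id in is_isotope:
                continue
            delta = candidate.mz - anchor.mz
            if delta <= 0:
                continue
            tol = anchor.mz * params.tol_ppm * 1e-6
            for z in params.charges:
                matched = False
                for k in range(1, params.max_isotopes + 1):
                    expected = k * ISOTOPE_SPACING / z
                    if abs(delta - expected) <= tol:
                        if candidate.apex_intensity <= (
                                params.isotope_max_ratio * anchor.apex_intensity):
                            new_annotations[candidate.id].append(
                                Annotation(
                                    kind=AnnotationKind.ISOTOPE,
                                    label=f"M+{k}",
                                    partner_id=anchor.id,
                                    score=profile_inner_product(anchor, candidate),
                                )
                            )
                            is_isotope.add(candidate.id)
                            matched = True
                        break
                if matched:
                    break
    out = [f.with_annotations(new_annotations[f.id]) for f in fs.features]
    return _rebuild(fs, out)


def annotate_adducts(fs: FeatureSet, rules: Sequence[AdductRule], mode: IonMode,
                     params: AnnotationParams = AnnotationParams()) -> FeatureSet:
    """Label adduct pairs and record the consensus neutral mass.

    For every ordered feature pair and every pair of distinct
    mode-applicable rules, if both features' implied neutral masses agree
    within ``tol_ppm``, both gain ADDUCT annotations naming their rules
    and each other.  The consensus neutral mass is the mean of all
    agreeing implied masses.
    """
    if not rules:
        raise ValueError("rules must be non-empty")
    applicable = [r for r in rules if r.applies_to(mode)]
    if not applicable:
        logger.warning("no adduct rule applies to ion mode %s; set unchanged",
                       mode.value)
        return fs
    members = [f for f in fs.features if not f.has_kind(AnnotationKind.ISOTOPE)]
    new_annotations: dict[int, list[Annotation]] = {f.id: [] for f in fs.features}
    agreeing_masses: list[float] = []
    for i, fa in enumerate(members):
        for fb in members[i + 1:]:
            for ra in applicable:
                for rb in applicable:
                    if ra is rb:
                        continue
                    na = ra.neutral_for_mz(fa.mz)
                    nb = rb.neutral_for_mz(fb.mz)
                    if na <= 0 or nb <= 0:
                        continue
                    if abs(na - nb) / na * 1e6 <= params.tol_ppm:
                        score = profile_inner_product(fa, fb)
                        new_annotations[fa.id].append(
                            Annotation(AnnotationKind.ADDUCT, ra.name,
                                       partner_id=fb.id, score=score))
                        new_annotations[fb.id].append(
                            Annotation(AnnotationKind.ADDUCT, rb.name,
                                       partner_id=fa.id, score=score))
                        agreeing_masses.extend((na, nb))
    consensus = (sum(agreeing_masses) / len(agreeing_masses)
                 if agreeing_masses else None)
    out = []
    for f in fs.features:
        # drop duplicate labels from multiple agreeing partners
        seen = {(a.kind, a.label, a.partner_id) for a in f.annotations}
        fresh = []
        for a in new_annotations[f.id]:
            key = (a.kind, a.label, a.partner_id)
            if key not in seen:
                seen.add(key)
                fresh.append(a)
        out.append(f.with_annotations(fresh))
    return _rebuild(fs, out, neutral_mass=consensus)


def match_reference(fs_list: Sequence[FeatureSet], library: Sequence[ReferenceEntry],
                    rules: Sequence[AdductRule], mode: IonMode,
                    tol_ppm: float = 5.0, rt_tol: float = 10.0) -> list[ReferenceMatch]:
    """Match feature sets against a reference library.

    A set matches an entry when some member's m/z is within ``tol_ppm`` of
    the entry's neutral mass transformed by a mode-applicable rule, and the
    set's rt agrees with the entry's expected rt within ``rt_tol`` (entries
    without an expected rt match on mass alone).  All candidates are
    returned, unranked; matched members gain IDENTITY annotations in the
    returned copies.
    """
    if not library:
        raise ValueError("library must be non-empty")
    applicable = [r for r in rules if r.applies_to(mode)]
    matches: list[ReferenceMatch] = []
    for fs in fs_list:
        for entry in library:
            if entry.ion_modes and mode is not IonMode.UNKNOWN \
                    and mode not in entry.ion_modes:
                continue
            rt_err = None
            if entry.expected_rt is not None:
                rt_err = abs(fs.rt - entry.expected_rt)
                if rt_err > rt_tol:
                    continue
            for rule in applicable:
                expected_mz = rule.mz_for_neutral(entry.neutral_mass)
                for f in fs.features:
                    err_ppm = abs(f.mz - expected_mz) / expected_mz * 1e6
                    if err_ppm <= tol_ppm:
                        annotated = f.with_annotations([
                            Annotation(AnnotationKind.IDENTITY, entry.name,
                                       score=1.0)])
                        new_members = tuple(annotated if g.id == f.id else g
                                            for g in fs.features)
                        fs = _rebuild(fs, new_members)
                        matches.append(ReferenceMatch(
                            feature_set=fs, entry=entry, rule=rule,
                            feature_id=f.id, mz_error_ppm=err_ppm,
                            rt_error_s=rt_err))
                        break
    return matches


_MAIN_PEAK_LABEL = {IonMode.POSITIVE: "M+H", IonMode.NEGATIVE: "M-H"}


def main_peak(fs: FeatureSet, mode: IonMode) -> Feature:
    """The main peak of a feature set: the M+H (positive) or M-H (negative)
    annotated member if present, otherwise the most intense non-isotope
    member (ties break to lowest m/z)."""
    label = _MAIN_PEAK_LABEL.get(mode)
    if label is not None:
        for f in fs.features:
            if any(a.kind is AnnotationKind.ADDUCT and a.label == label
                   for a in f.annotations):
                return f
    candidates = [f for f in fs.features if not f.has_kind(AnnotationKind.ISOTOPE)]
    if not candidates:
        candidates = list(fs.features)
    return max(candidates, key=lambda f: (f.apex_intensity, -f.mz))
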