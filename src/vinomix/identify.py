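"""Compound annotation: pseudo-spectra, library match factor, retention index.

Significant features that co-elute are grouped into pseudo-spectra; each is
scored against a reference library with a NIST-style weighted-cosine identity
match factor (0–999) and, where an alkane ladder is available, its retention
index is computed in the van den Dool–Kratz linear form (the convention for
temperature-programmed GC; the isothermal logarithmic form is available behind
a flag). Annotation is two-step: a hit is tentative only if the match factor
reaches the threshold AND the calculated RI agrees with the library RI within
tolerance. A further step compares a hit against an authentic-standard run for
full confirmation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import Feature
from .synthio import LibrarySpectrum, Run

__all__ = [
    "AlkaneLadder",
    "PseudoSpectrum",
    "IdentificationHit",
    "build_pseudospectra",
    "match_factor",
    "compute_retention_index",
    "two_step_confirm",
    "confirm_with_standard",
    "hits_to_dataframe",
]


@dataclass(frozen=True)
class AlkaneLadder:
    """C7–C30 n-alkane retention times anchoring the retention-index scale."""

    entries: tuple[tuple[int, float], ...]  # (carbon number, rt minutes)

    def __post_init__(self) -> None:
        ent = tuple(sorted((int(n), float(rt)) for n, rt in self.entries))
        if len(ent) < 2:
            raise ValueError("ladder needs at least two alkanes")
        rts = [rt for _, rt in ent]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("ladder retention times must increase strictly with carbon number")
        object.__setattr__(self, "entries", ent)

    @classmethod
    def from_mapping(cls, ladder: Mapping[int, float]) -> "AlkaneLadder":
        return cls(tuple(ladder.items()))

    @classmethod
    def from_csv(cls, path) -> "AlkaneLadder":
        df = pd.read_csv(path)
        return cls(tuple((int(r.carbon), float(r.rt)) for r in df.itertuples()))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.entries, columns=["carbon", "rt"]).to_csv(path, index=False)

    @property
    def carbons(self) -> np.ndarray:
        return np.array([n for n, _ in self.entries])

    @property
    def rts(self) -> np.ndarray:
        return np.array([rt for _, rt in self.entries])


@dataclass
class PseudoSpectrum:
    """Composite spectrum of co-eluting features attributed to one compound."""

    rt: float
    member_features: list[str]
    spectrum: tuple[tuple[int, float], ...]  # (mz, intensity scaled to max 999)


@dataclass
class IdentificationHit:
    pseudo_spectrum: PseudoSpectrum
    compound: str | None
    match_factor: int
    ri_calc: float | None
    ri_lit: float | None
    delta_ri: float | None
    status: str  # tentative | confirmed | rejected | orphan


def build_pseudospectra(
    features: Sequence[Feature], gap_s: float = 3.0
) -> list[PseudoSpectrum]:
    """Single-linkage clustering of features on rtmed: a new pseudo-spectrum
    starts wherever the gap to the previous feature exceeds ``gap_s`` seconds.
    Each cluster's spectrum is the members' (mz, mean intensity across
    samples), rescaled so the base peak is 999."""
    if not features:
        return []
    feats = sorted(features, key=lambda f: f.rtmed)
    clusters: list[list[Feature]] = [[feats[0]]]
    for f in feats[1:]:
        if (f.rtmed - clusters[-1][-1].rtmed) * 60.0 > gap_s:
            clusters.append([f])
        else:
            clusters[-1].append(f)
    out = []
    for cl in clusters:
        ions: dict[int, float] = {}
        for f in cl:
            mean_int = float(np.mean(list(f.intensity.values()))) if f.intensity else 0.0
            ions[f.mzmed] = ions.get(f.mzmed, 0.0) + mean_int
        top = max(ions.values())
        if top <= 0:
            continue
        spectrum = tuple(sorted((mz, 999.0 * v / top) for mz, v in ions.items()))
        out.append(
            PseudoSpectrum(
                rt=float(np.median([f.rtmed for f in cl])),
                member_features=[f.feature_id for f in cl],
                spectrum=spectrum,
            )
        )
    return out


def match_factor(
    query: Sequence[tuple[int, float]],
    reference: Sequence[tuple[int, float]],
    intensity_power: float = 0.5,
    mz_power: float = 1.0,
) -> int:
    """NIST-style identity match factor between two nominal-mass spectra.

    Each peak gets weight ``W = intensity**0.5 * mz``; the score is
    ``round(999 * (Σ_matched Wq·Wr)² / (ΣWq² · ΣWr²))`` with m/z matched
    exactly at nominal mass. Symmetric, invariant to uniform intensity
    scaling, 999 iff the spectra are proportional on the union of their m/z.
    """
    if not query or not reference:
        raise ValueError("match_factor requires two non-empty spectra")

    def weights(spec: Sequence[tuple[int, float]]) -> dict[int, float]:
        w: dict[int, float] = {}
        for mz, inten in spec:
            if inten < 0:
                raise ValueError("negative intensity in spectrum")
            w[int(mz)] = w.get(int(mz), 0.0) + (inten**intensity_power) * (int(mz) ** mz_power)
        return w

    wq = weights(query)
    wr = weights(reference)
    dot = sum(wq[m] * wr[m] for m in wq.keys() & wr.keys())
    nq = sum(v * v for v in wq.values())
    nr = sum(v * v for v in wr.values())
    if nq == 0 or nr == 0:
        return 0
    return int(round(999.0 * (dot * dot) / (nq * nr)))


def compute_retention_index(
    rt: float, ladder: AlkaneLadder | Mapping[int, float], form: str = "linear", dead_time: float = 0.0
) -> float:
    """Retention index of ``rt`` (minutes) against the alkane ladder.

    ``form='linear'`` is the van den Dool–Kratz expression for
    temperature-programmed runs: RI = 100·n + 100·(rt − rt_n)/(rt_{n+1} − rt_n)
    between the bracketing alkanes. ``form='kovats'`` uses the isothermal
    logarithmic equation on adjusted retention times (rt − dead_time).
    Extrapolation beyond the ladder is refused.
    """
    if isinstance(ladder, Mapping):
        ladder = AlkaneLadder.from_mapping(ladder)
    ns = ladder.carbons
    rts = ladder.rts
    if rt < rts[0] or rt > rts[-1]:
        raise ValueError(f"RI extrapolation refused: rt {rt:.3f} min outside ladder [{rts[0]:.3f}, {rts[-1]:.3f}]")
    i = int(np.searchsorted(rts, rt, side="right")) - 1
    i = min(max(i, 0), len(ns) - 2)
    n, rt_n, rt_n1 = ns[i], rts[i], rts[i + 1]
    if form == "linear":
        return 100.0 * n + 100.0 * (ns[i + 1] - n) * (rt - rt_n) / (rt_n1 - rt_n)
    if form == "kovats":
        t, t_n, t_n1 = rt - dead_time, rt_n - dead_time, rt_n1 - dead_time
        if min(t, t_n, t_n1) <= 0:
            raise ValueError("adjusted retention times must be positive for the logarithmic form")
        return 100.0 * n + 100.0 * (ns[i + 1] - n) * (math.log(t) - math.log(t_n)) / (
            math.log(t_n1) - math.log(t_n)
        )
    raise ValueError(f"unknown retention-index form {form!r}")


def two_step_confirm(
    pseudospectra: Sequence[PseudoSpectrum],
    library: Sequence[LibrarySpectrum],
    ladder: AlkaneLadder | Mapping[int, float] | None = None,
    min_match: int = 700,
    ri_tolerance: float = 15.0,
) -> list[IdentificationHit]:
    """Two-step annotation of pseudo-spectra.

    Step one: best library entry by match factor (ties broken by smaller
    |ΔRI|). Step two: the hit is ``tentative`` iff match ≥ ``min_match`` AND
    the library RI is absent or |RI_calc − RI_lit| ≤ ``ri_tolerance``; a good
    spectral match with a bad RI is ``rejected``; a best match below the
    threshold is an ``orphan``.
    """
    if ladder is not None and isinstance(ladder, Mapping):
        ladder = AlkaneLadder.from_mapping(ladder)
    hits: list[IdentificationHit] = []
    for ps in pseudospectra:
        ri_calc: float | None = None
        if ladder is not None:
            try:
                ri_calc = compute_retention_index(ps.rt, ladder)
            except ValueError:
                ri_calc = None
        best: LibrarySpectrum | None = None
        best_score = -1
        best_dri = math.inf
        for entry in library:
            score = match_factor(ps.spectrum, entry.peaks)
            dri = (
                abs(ri_calc - entry.ri_lit)
                if (ri_calc is not None and entry.ri_lit is not None)
                else math.inf
            )
            if score > best_score or (score == best_score and dri < best_dri):
                best, best_score, best_dri = entry, score, dri
        if best is None or best_score < min_match:
            hits.append(
                IdentificationHit(ps, best.name if best else None, max(best_score, 0), ri_calc, None, None, "orphan")
            )
            continue
        delta = None
        if ri_calc is not None and best.ri_lit is not None:
            delta = ri_calc - best.ri_lit
        if delta is None or abs(delta) <= ri_tolerance:
            status = "tentative"
        else:
            status = "rejected"
        hits.append(IdentificationHit(ps, best.name, best_score, ri_calc, best.ri_lit, delta, status))
    return hits


def confirm_with_standard(
    hit: IdentificationHit,
    standard_run: Run,
    rt_tolerance_s: float = 3.0,
    min_match: int = 700,
    gap_s: float = 3.0,
    detection_params=None,
) -> str:
    """Confirm a tentative hit against an authentic-standard run.

    The standard run is processed through peak detection; the detected peaks
    nearest the hit's retention time are assembled into a spectrum. The hit is
    ``confirmed`` iff the standard elutes within ``rt_tolerance_s`` of the
    hit AND the spectra match with factor ≥ ``min_match``; otherwise
    ``rejected``. Raises if the standard run shows no detected peak near the
    expected time.
    """
    from .features import detect_peaks

    peaks = detect_peaks(standard_run, detection_params)
    if not peaks:
        raise ValueError(f"standard run {standard_run.meta.run_id} has no detected peaks")
    # nearest cluster of peaks to the hit rt
    near = [p for p in peaks if abs(p.rt - hit.pseudo_spectrum.rt) * 60.0 <= max(rt_tolerance_s * 3, 10.0)]
    if not near:
        nearest = min(peaks, key=lambda p: abs(p.rt - hit.pseudo_spectrum.rt))
        near = [p for p in peaks if abs(p.rt - nearest.rt) * 60.0 <= gap_s]
    apex_rt = float(near[int(np.argmax([p.height for p in near]))].rt)
    cluster = [p for p in near if abs(p.rt - apex_rt) * 60.0 <= gap_s]
    ions: dict[int, float] = {}
    for p in cluster:
        ions[p.mz] = ions.get(p.mz, 0.0) + p.area
    top = max(ions.values())
    spectrum = tuple(sorted((mz, 999.0 * v / top) for mz, v in ions.items()))
    if abs(apex_rt - hit.pseudo_spectrum.rt) * 60.0 > rt_tolerance_s:
        return "rejected"
    if match_factor(hit.pseudo_spectrum.spectrum, spectrum) < min_match:
        return "rejected"
    return "confirmed"


def hits_to_dataframe(hits: Sequence[IdentificationHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rt": h.pseudo_spectrum.rt,
                "members": ";".join(h.pseudo_spectrum.member_features),
                "compound": h.compound,
                "match_factor": h.match_factor,
                "ri_calc": h.ri_calc,
                "ri_lit": h.ri_lit,
                "delta_ri": h.delta_ri,
                "status": h.status,
            }
            for h in hits
        ]
    )
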