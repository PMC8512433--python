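"""Synthetic study generation and standard-format IO for GC-MS volatile metabolomics.

This module provides (a) readers/writers for the formats the workflow consumes —
centroided MS1 mzML runs, MSP spectral libraries, metadata / truth CSV tables and
YAML study recipes — and (b) a simulator that generates whole multi-sample
headspace GC-MS studies with known ground truth: Gaussian elution profiles placed
by retention index against a C7–C30 alkane ladder, multiplicative treatment
effects, log-normal biological variation, per-run retention drift, Poisson-like
detector noise and spiked internal standards.

The simulator is the test bed for every downstream stage: because the true
compound-by-sample concentration table is returned alongside the runs, peak
detection, differential statistics, identification and quantitation can all be
checked against planted truth.
"""

from __future__ import annotations

import base64
import math
import zlib  # noqa: F401  (kept for parity with common mzML writers; we write uncompressed)
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ROOTSTOCKS",
    "IRRIGATIONS",
    "SampleMeta",
    "CompoundSpec",
    "LibrarySpectrum",
    "StudyRecipe",
    "Run",
    "ri_to_rt",
    "simulate_study",
    "simulate_calibration_runs",
    "write_runs",
    "read_runs",
    "write_library",
    "read_library",
    "write_metadata",
    "read_metadata",
    "save_recipe",
    "load_recipe",
    "default_design",
    "default_ladder",
    "default_study_recipe",
    "default_library",
    "default_thresholds",
    "INTERNAL_STANDARDS",
    "NAMED_COMPOUNDS",
]

ROOTSTOCKS = ("Own", "1103P", "3309C", "SO4")
IRRIGATIONS = ("Full", "RDI", "None")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one injection of one biological (wine) sample."""

    sample_id: str
    rootstock: str
    irrigation: str
    year: int
    vine: int
    injection: int = 1

    def __post_init__(self) -> None:
        if self.rootstock not in ROOTSTOCKS:
            raise ValueError(f"unknown rootstock {self.rootstock!r}; expected one of {ROOTSTOCKS}")
        if self.irrigation not in IRRIGATIONS:
            raise ValueError(f"unknown irrigation {self.irrigation!r}; expected one of {IRRIGATIONS}")

    @property
    def run_id(self) -> str:
        """Unique identifier of this injection (technical replicate)."""
        return f"{self.sample_id}_inj{self.injection}"


@dataclass(frozen=True)
class LibrarySpectrum:
    """A reference EI spectrum with an optional literature retention index.

    Peaks are stored sorted by m/z and rescaled so the base peak is 999,
    the convention of EI library formats.
    """

    name: str
    peaks: tuple[tuple[int, float], ...]
    ri_lit: float | None = None

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError(f"library spectrum {self.name!r} has no peaks")
        pk = sorted((int(mz), float(i)) for mz, i in self.peaks)
        top = max(i for _, i in pk)
        if top <= 0:
            raise ValueError(f"library spectrum {self.name!r} has no positive intensity")
        pk = tuple((mz, 999.0 * i / top) for mz, i in pk)
        object.__setattr__(self, "peaks", pk)

    @property
    def mz(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks], dtype=int)

    @property
    def intensity(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks], dtype=float)


@dataclass
class CompoundSpec:
    """Ground-truth description of one volatile compound in a synthetic study.

    Parameters
    ----------
    name : str
    spectrum : sequence of (mz, relative intensity)
        Nominal-mass EI spectrum, base peak 999.
    true_ri : float
        Retention index on the simulated column; converted to a retention time
        through the alkane ladder.
    base_conc : float
        Reference concentration in µg/L (the concentration of a sample whose
        factor levels all have multiplier 1).
    effect_multiplier : mapping of factor level -> float
        Multiplicative treatment effect, e.g. ``{"Own": 1.3}`` raises the
        concentration 30 % in own-rooted samples.
    cv : float
        Biological coefficient of variation; concentrations are multiplied by a
        log-normal factor with mean 1 and this CV.
    odor_threshold : float or None
        Odor threshold in µg/L, used downstream for odor activity values.
    response : float
        Detector response: base-ion peak area (counts·s) per µg/L.
    """

    name: str
    spectrum: tuple[tuple[int, float], ...]
    true_ri: float
    base_conc: float
    effect_multiplier: dict[str, float] = field(default_factory=dict)
    cv: float = 0.0
    odor_threshold: float | None = None
    response: float = 200.0

    def __post_init__(self) -> None:
        if not self.spectrum:
            raise ValueError(f"compound {self.name!r}: spectrum must be non-empty")
        spec = tuple((int(mz), float(i)) for mz, i in self.spectrum)
        ints = [i for _, i in spec]
        if min(ints) < 0 or max(ints) > 999:
            raise ValueError(f"compound {self.name!r}: intensities must lie in [0, 999]")
        if not math.isclose(max(ints), 999.0, rel_tol=1e-9):
            raise ValueError(f"compound {self.name!r}: base peak intensity must be 999")
        if self.base_conc <= 0:
            raise ValueError(f"compound {self.name!r}: base_conc must be > 0")
        if any(m <= 0 for m in self.effect_multiplier.values()):
            raise ValueError(f"compound {self.name!r}: effect multipliers must be > 0")
        self.spectrum = spec

    def expected_concentration(self, meta: SampleMeta) -> float:
        """Noise-free concentration for a sample with the given factor levels."""
        mult = 1.0
        for level in (meta.rootstock, meta.irrigation):
            mult *= self.effect_multiplier.get(level, 1.0)
        return self.base_conc * mult

    def as_library_spectrum(self, ri_lit: float | None = None) -> LibrarySpectrum:
        return LibrarySpectrum(self.name, self.spectrum, self.true_ri if ri_lit is None else ri_lit)


@dataclass
class Run:
    """One GC-MS injection: time-ordered centroid scans of (m/z, intensity)."""

    meta: SampleMeta
    scans: list[tuple[float, np.ndarray, np.ndarray]]

    def validate(self) -> None:
        last = -np.inf
        for i, (rt, mz, inten) in enumerate(self.scans):
            if rt <= last:
                raise ValueError(f"run {self.meta.run_id}: scan {i} time {rt} not strictly increasing")
            if len(mz) != len(inten):
                raise ValueError(f"run {self.meta.run_id}: scan {i} m/z and intensity length mismatch")
            if len(inten) and np.min(inten) < 0:
                raise ValueError(f"run {self.meta.run_id}: scan {i} has negative intensity")
            last = rt

    @property
    def times(self) -> np.ndarray:
        return np.array([rt for rt, _, _ in self.scans])

    def tic(self) -> np.ndarray:
        """Total ion current per scan."""
        return np.array([float(np.sum(inten)) for _, _, inten in self.scans])


@dataclass
class StudyRecipe:
    """Full description of a synthetic GC-MS study.

    ``ladder`` maps alkane carbon number (7..30) to its retention time in
    minutes and anchors the retention-index scale. ``scan_hz`` is in scans per
    minute; ``rt_range`` is the acquisition window in minutes. A fixed ``seed``
    makes the simulated study byte-identical across runs.
    """

    design: list[SampleMeta]
    compounds: list[CompoundSpec]
    internal_standards: list[tuple[str, float]]
    ladder: dict[int, float]
    rt_drift_sd: float = 0.01
    noise_floor: float = 0.0
    scan_hz: float = 120.0
    rt_range: tuple[float, float] = (0.5, 39.5)
    peak_sigma_s: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        ns = sorted(self.ladder)
        rts = [self.ladder[n] for n in ns]
        if len(ns) < 2:
            raise ValueError("ladder needs at least two alkanes")
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("ladder retention times must be strictly increasing in carbon number")
        seen = set()
        for m in self.design:
            key = (m.sample_id, m.injection)
            if key in seen:
                raise ValueError(f"duplicate (sample_id, injection) {key}")
            seen.add(key)
        if self.scan_hz <= 0:
            raise ValueError("scan_hz must be positive")
        lo, hi = self.rt_range
        if hi <= lo:
            raise ValueError("rt_range must be an increasing (start, end) pair in minutes")

    @property
    def biological_ids(self) -> list[str]:
        out: list[str] = []
        for m in self.design:
            if m.sample_id not in out:
                out.append(m.sample_id)
        return out

    def internal_standard_specs(self) -> list[CompoundSpec]:
        specs = []
        for name, conc in self.internal_standards:
            if name not in INTERNAL_STANDARDS:
                raise KeyError(f"no built-in spectrum for internal standard {name!r}")
            base = INTERNAL_STANDARDS[name]
            specs.append(replace(base, base_conc=conc))
        return specs


# ---------------------------------------------------------------------------
# retention index <-> retention time
# ---------------------------------------------------------------------------


def ri_to_rt(ri: float, ladder: Mapping[int, float]) -> float:
    """Map a retention index to a retention time by piecewise-linear
    interpolation between alkane ladder points (inverse of the van den
    Dool–Kratz convention used at identification time)."""
    ns = np.array(sorted(ladder), dtype=float)
    rts = np.array([ladder[int(n)] for n in ns], dtype=float)
    ris = 100.0 * ns
    if ri < ris[0] or ri > ris[-1]:
        raise ValueError(
            f"RI out of ladder range: {ri} not in [{ris[0]:.0f}, {ris[-1]:.0f}]"
        )
    return float(np.interp(ri, ris, rts))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative noise factor with mean exactly 1 and the given CV."""
    if cv <= 0:
        return 1.0
    sigma2 = math.log(1.0 + cv * cv)
    return float(rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2)))


def simulate_study(recipe: StudyRecipe) -> tuple[list[Run], pd.DataFrame]:
    """Simulate every injection of a study and return (runs, truth table).

    The truth table is a compound × biological-sample DataFrame of true
    concentrations in µg/L (technical replicates of one sample share the same
    true concentration; only retention drift and detector noise differ).

    Each compound elutes as a Gaussian profile (sigma ``peak_sigma_s``) centred
    at ``ri_to_rt(true_ri) + drift``; its per-ion chromatographic area equals
    ``conc × response × rel_intensity/999`` counts·s exactly (the sampled
    profile is renormalised so the discrete trapezoid matches the target area).
    With ``noise_floor > 0`` intensities are Poisson counts around
    signal + floor; with 0 the output is noise-free and deterministic even
    across seeds.
    """
    rng = np.random.default_rng(recipe.seed)
    bio = recipe.biological_ids
    by_bio: dict[str, SampleMeta] = {}
    for m in recipe.design:
        by_bio.setdefault(m.sample_id, m)

    # true concentrations, drawn compound-major for reproducibility
    truth = pd.DataFrame(index=[c.name for c in recipe.compounds], columns=bio, dtype=float)
    for c in recipe.compounds:
        for sid in bio:
            truth.loc[c.name, sid] = c.expected_concentration(by_bio[sid]) * _lognormal_factor(rng, c.cv)
    truth.index.name = "compound"

    is_specs = recipe.internal_standard_specs()
    all_specs = list(recipe.compounds) + is_specs
    # fail fast on compounds outside the ladder
    for spec in all_specs:
        ri_to_rt(spec.true_ri, recipe.ladder)

    lo, hi = recipe.rt_range
    dt = 1.0 / recipe.scan_hz
    times = np.arange(lo, hi, dt)
    t_sec = times * 60.0
    channels = np.array(sorted({mz for spec in all_specs for mz, _ in spec.spectrum}), dtype=int)
    ch_index = {mz: i for i, mz in enumerate(channels)}
    sigma_min = recipe.peak_sigma_s / 60.0

    runs: list[Run] = []
    for meta in recipe.design:
        drift = float(rng.normal(0.0, recipe.rt_drift_sd)) if recipe.rt_drift_sd > 0 else 0.0
        mat = np.zeros((times.size, channels.size))
        for spec in all_specs:
            conc = (
                float(truth.loc[spec.name, meta.sample_id])
                if spec.name in truth.index
                else spec.base_conc  # internal standards: fixed spike level
            )
            rt_c = ri_to_rt(spec.true_ri, recipe.ladder) + drift
            g = np.exp(-0.5 * ((times - rt_c) / sigma_min) ** 2)
            area = np.trapezoid(g, t_sec)
            if area <= 0:
                continue
            u = g / area  # discrete trapezoid over seconds == 1
            for mz, rel in spec.spectrum:
                mat[:, ch_index[mz]] += conc * spec.response * (rel / 999.0) * u
        if recipe.noise_floor > 0:
            mat = rng.poisson(mat + recipe.noise_floor).astype(float)
        run = Run(meta=meta, scans=[(float(t), channels, mat[i]) for i, t in enumerate(times)])
        runs.append(run)
    return runs, truth


def simulate_calibration_runs(
    recipe: StudyRecipe,
    compounds: Sequence[CompoundSpec] | None = None,
    levels_rel: Sequence[float] = (0.2, 0.5, 1.0, 2.0, 4.0),
) -> tuple[list[Run], pd.DataFrame]:
    """Simulate calibration-series runs: each run holds every calibrated
    compound at ``base_conc × level`` plus the internal standards, with no
    biological variation, no treatment effects and no retention drift.

    Returns the runs and a long-format level table (compound, level, conc_ugL).
    These emulate the authentic-standard mixtures used to build calibration
    curves, and double as the "authentic standard runs" for confirmation.
    """
    cal_compounds = list(compounds) if compounds is not None else list(recipe.compounds)
    rows = []
    runs: list[Run] = []
    for li, rel in enumerate(levels_rel, start=1):
        pure = [
            replace(c, effect_multiplier={}, cv=0.0, base_conc=c.base_conc * rel)
            for c in cal_compounds
        ]
        meta = SampleMeta(f"cal_L{li}", "Own", "Full", 0, 0, 1)
        sub = StudyRecipe(
            design=[meta],
            compounds=pure,
            internal_standards=recipe.internal_standards,
            ladder=recipe.ladder,
            rt_drift_sd=0.0,
            noise_floor=recipe.noise_floor,
            scan_hz=recipe.scan_hz,
            rt_range=recipe.rt_range,
            peak_sigma_s=recipe.peak_sigma_s,
            seed=recipe.seed + 90000 + li,
        )
        level_runs, _ = simulate_study(sub)
        runs.extend(level_runs)
        for c, p in zip(cal_compounds, pure):
            rows.append({"compound": c.name, "level": li, "run_id": meta.run_id, "conc_ugL": p.base_conc})
    return runs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mzML IO
# ---------------------------------------------------------------------------

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="{run_id}">
    <spectrumList count="{count}" defaultDataProcessingRef="dp">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode("ascii")


def _spectrum_xml(index: int, rt_min: float, mz: np.ndarray, inten: np.ndarray) -> str:
    mz64 = _b64(mz)
    in64 = _b64(inten)
    n = len(mz)
    # scan start time written in seconds, full decimal precision
    return (
        f'      <spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{n}">\n'
        f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>\n'
        f'        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>\n'
        f"        <scanList count=\"1\">\n"
        f"          <scan>\n"
        f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt_min * 60.0!r}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>\n'
        f"          </scan>\n"
        f"        </scanList>\n"
        f'        <binaryDataArrayList count="2">\n'
        f'          <binaryDataArray encodedLength="{len(mz64)}">\n'
        f'            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
        f'            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
        f'            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
        f"            <binary>{mz64}</binary>\n"
        f"          </binaryDataArray>\n"
        f'          <binaryDataArray encodedLength="{len(in64)}">\n'
        f'            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
        f'            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
        f'            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>\n'
        f"            <binary>{in64}</binary>\n"
        f"          </binaryDataArray>\n"
        f"        </binaryDataArrayList>\n"
        f"      </spectrum>\n"
    )


def write_runs(runs: Sequence[Run], directory: str | Path) -> list[Path]:
    """Write each run to ``<directory>/<run_id>.mzML`` (centroid MS1, 64-bit
    float arrays, no compression). Returns the list of written paths; an empty
    run list writes nothing and returns an empty manifest."""
    directory = Path(directory)
    if runs:
        directory.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for run in runs:
        run.validate()
        path = directory / f"{run.meta.run_id}.mzML"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(_MZML_HEADER.format(run_id=run.meta.run_id, count=len(run.scans)))
            for i, (rt, mz, inten) in enumerate(run.scans):
                fh.write(_spectrum_xml(i, rt, mz, inten))
            fh.write(_MZML_FOOTER)
        paths.append(path)
    return paths


def _decode_binary(node, ns: str) -> np.ndarray:
    accessions = {
        p.get("accession") for p in node.findall(f"{ns}cvParam")
    }
    text = node.findtext(f"{ns}binary") or ""
    raw = base64.b64decode(text)
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_runs(
    paths: Iterable[str | Path], metadata: Sequence[SampleMeta] | None = None
) -> list[Run]:
    """Read centroid MS1 mzML files back into :class:`Run` objects.

    If ``metadata`` is given, each file's stem is matched against
    ``SampleMeta.run_id``; otherwise a placeholder meta is attached. Raises a
    ``ValueError`` naming the file and scan for non-monotone scan times, and a
    parse error naming the file for malformed XML.
    """
    from lxml import etree

    meta_by_run = {m.run_id: m for m in metadata} if metadata else {}
    runs: list[Run] = []
    for path in paths:
        path = Path(path)
        scans: list[tuple[float, np.ndarray, np.ndarray]] = []
        try:
            tree = etree.parse(str(path))
            root = tree.getroot()
            ns = f"{{{root.nsmap.get(None, '')}}}" if root.nsmap.get(None) else ""
            for i, spec in enumerate(root.iter(f"{ns}spectrum")):
                rt_min = None
                for cv in spec.iter(f"{ns}cvParam"):
                    if cv.get("accession") == "MS:1000016":
                        value = float(cv.get("value"))
                        unit = (cv.get("unitName") or "second").lower()
                        rt_min = value / 60.0 if unit.startswith("s") else value
                if rt_min is None:
                    raise ValueError(f"spectrum {i} has no scan start time")
                mz_arr = inten_arr = None
                for bda in spec.iter(f"{ns}binaryDataArray"):
                    accs = {p.get("accession") for p in bda.findall(f"{ns}cvParam")}
                    if "MS:1000514" in accs:
                        mz_arr = _decode_binary(bda, ns)
                    elif "MS:1000515" in accs:
                        inten_arr = _decode_binary(bda, ns)
                if mz_arr is None or inten_arr is None:
                    raise ValueError(f"spectrum {i} lacks m/z or intensity arrays")
                scans.append((rt_min, mz_arr, inten_arr))
        except (ValueError, KeyError, etree.XMLSyntaxError) as exc:
            raise ValueError(f"malformed mzML file {path}: {exc}") from exc
        for i in range(1, len(scans)):
            if scans[i][0] <= scans[i - 1][0]:
                raise ValueError(f"malformed mzML file {path}: scan {i} time not strictly increasing")
        stem = path.stem
        meta = meta_by_run.get(stem)
        if meta is None:
            meta = SampleMeta(stem, "Own", "Full", 0, 0, 1)
        runs.append(Run(meta=meta, scans=scans))
    return runs


# ---------------------------------------------------------------------------
# MSP spectral library IO
# ---------------------------------------------------------------------------


def write_library(specs: Sequence[LibrarySpectrum | CompoundSpec], path: str | Path) -> Path:
    """Write spectra to an MSP file with Name / RI / Num Peaks records."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for spec in specs:
            if isinstance(spec, CompoundSpec):
                spec = spec.as_library_spectrum()
            fh.write(f"Name: {spec.name}\n")
            if spec.ri_lit is not None:
                fh.write(f"RI: {spec.ri_lit:g}\n")
            fh.write(f"Num Peaks: {len(spec.peaks)}\n")
            for i in range(0, len(spec.peaks), 5):
                chunk = spec.peaks[i : i + 5]
                fh.write("; ".join(f"{mz} {inten:.1f}" for mz, inten in chunk) + "\n")
            fh.write("\n")
    return path


def read_library(path: str | Path) -> list[LibrarySpectrum]:
    """Parse an MSP spectral library.

    Raises ``ValueError`` naming the offending record when 'Num Peaks' is
    missing or does not match the number of (mz, intensity) pairs.
    """
    path = Path(path)
    out: list[LibrarySpectrum] = []
    blocks: list[list[str]] = [[]]
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.strip() == "":
            if blocks[-1]:
                blocks.append([])
        else:
            blocks[-1].append(line)
    for block in blocks:
        if not block:
            continue
        name: str | None = None
        ri: float | None = None
        num_peaks: int | None = None
        pairs: list[tuple[int, float]] = []
        for line in block:
            low = line.lower()
            if low.startswith("name:"):
                name = line.split(":", 1)[1].strip()
            elif low.startswith("ri:") or low.startswith("retentionindex:"):
                ri = float(line.split(":", 1)[1].strip())
            elif low.startswith("num peaks:"):
                num_peaks = int(line.split(":", 1)[1].strip())
            elif ":" in line and not line[0].isdigit():
                continue  # other metadata fields are ignored
            else:
                for token in line.replace(";", "\n").splitlines():
                    token = token.strip()
                    if not token:
                        continue
                    bits = token.replace(",", " ").split()
                    if len(bits) < 2:
                        raise ValueError(f"MSP record {name!r}: cannot parse peak line {line!r}")
                    pairs.append((int(float(bits[0])), float(bits[1])))
        label = name if name is not None else "<unnamed>"
        if name is None:
            raise ValueError("MSP record without a Name field")
        if num_peaks is None:
            raise ValueError(f"MSP record {label!r}: missing 'Num Peaks'")
        if num_peaks != len(pairs):
            raise ValueError(
                f"MSP record {label!r}: 'Num Peaks: {num_peaks}' but {len(pairs)} pairs found"
            )
        out.append(LibrarySpectrum(name=name, peaks=tuple(pairs), ri_lit=ri))
    return out


# ---------------------------------------------------------------------------
# metadata / recipe IO
# ---------------------------------------------------------------------------

_META_COLS = ["sample_id", "rootstock", "irrigation", "year", "vine", "injection"]


def write_metadata(design: Sequence[SampleMeta], path: str | Path) -> Path:
    df = pd.DataFrame(
        [[m.sample_id, m.rootstock, m.irrigation, m.year, m.vine, m.injection] for m in design],
        columns=_META_COLS,
    )
    df.to_csv(path, index=False)
    return Path(path)


def read_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata CSV {path}: missing columns {missing}")
    return [
        SampleMeta(
            str(r.sample_id), str(r.rootstock), str(r.irrigation), int(r.year), int(r.vine), int(r.injection)
        )
        for r in df.itertuples()
    ]


def save_recipe(recipe: StudyRecipe, path: str | Path) -> Path:
    doc = {
        "seed": recipe.seed,
        "rt_drift_sd": recipe.rt_drift_sd,
        "noise_floor": recipe.noise_floor,
        "scan_hz": recipe.scan_hz,
        "rt_range": list(recipe.rt_range),
        "peak_sigma_s": recipe.peak_sigma_s,
        "ladder": {int(k): float(v) for k, v in recipe.ladder.items()},
        "internal_standards": [[n, float(c)] for n, c in recipe.internal_standards],
        "design": [
            {
                "sample_id": m.sample_id,
                "rootstock": m.rootstock,
                "irrigation": m.irrigation,
                "year": m.year,
                "vine": m.vine,
                "injection": m.injection,
            }
            for m in recipe.design
        ],
        "compounds": [
            {
                "name": c.name,
                "spectrum": [[int(mz), float(i)] for mz, i in c.spectrum],
                "true_ri": c.true_ri,
                "base_conc": c.base_conc,
                "effect_multiplier": dict(c.effect_multiplier),
                "cv": c.cv,
                "odor_threshold": c.odor_threshold,
                "response": c.response,
            }
            for c in recipe.compounds
        ],
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
    return path


def load_recipe(path: str | Path) -> StudyRecipe:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    design = [SampleMeta(**d) for d in doc["design"]]
    compounds = [
        CompoundSpec(
            name=c["name"],
            spectrum=tuple((int(mz), float(i)) for mz, i in c["spectrum"]),
            true_ri=float(c["true_ri"]),
            base_conc=float(c["base_conc"]),
            effect_multiplier={k: float(v) for k, v in (c.get("effect_multiplier") or {}).items()},
            cv=float(c.get("cv", 0.0)),
            odor_threshold=c.get("odor_threshold"),
            response=float(c.get("response", 200.0)),
        )
        for c in doc["compounds"]
    ]
    return StudyRecipe(
        design=design,
        compounds=compounds,
        internal_standards=[(n, float(c)) for n, c in doc["internal_standards"]],
        ladder={int(k): float(v) for k, v in doc["ladder"].items()},
        rt_drift_sd=float(doc.get("rt_drift_sd", 0.01)),
        noise_floor=float(doc.get("noise_floor", 0.0)),
        scan_hz=float(doc.get("scan_hz", 120.0)),
        rt_range=tuple(doc.get("rt_range", (0.5, 39.5))),
        peak_sigma_s=float(doc.get("peak_sigma_s", 2.5)),
        seed=int(doc.get("seed", 0)),
    )


# ---------------------------------------------------------------------------
# built-in study: wine volatiles under rootstock x irrigation treatments
# ---------------------------------------------------------------------------

# Internal standards spiked into every sample: 2-octanol at 50 ppb normalises
# response; the other two are QC standards.
INTERNAL_STANDARDS: dict[str, CompoundSpec] = {
    "4-Methyl-2-pentanol": CompoundSpec(
        "4-Methyl-2-pentanol", ((41, 320), (43, 780), (45, 999), (69, 240), (87, 70)), 735, 100.0
    ),
    "3-Octanone": CompoundSpec(
        "3-Octanone", ((43, 999), (57, 620), (72, 410), (99, 350), (128, 110)), 980, 50.0
    ),
    "2-Octanol": CompoundSpec(
        "2-Octanol", ((41, 300), (45, 999), (55, 480), (97, 190), (112, 45)), 1001, 50.0
    ),
}

# name, EI spectrum, true RI, base concentration µg/L, odor threshold µg/L,
# treatment multipliers. Twelve compounds carry >= 25 % rootstock shifts;
# beta-damascenone carries the subtle ~10 % own-rooted elevation and an RDI
# bump that the study design is meant to resolve at the quantitation stage.
NAMED_COMPOUNDS: list[tuple[str, tuple[tuple[int, int], ...], float, float, float | None, dict[str, float]]] = [
    ("Ethyl butanoate", ((29, 250), (43, 620), (71, 999), (88, 180), (101, 60)), 805, 120.0, 20.0, {}),
    ("Isoamyl acetate", ((43, 999), (55, 310), (70, 560), (87, 140), (130, 20)), 878, 495.0, 30.0, {}),
    ("Isoamyl alcohol", ((41, 450), (42, 330), (55, 999), (57, 400), (70, 310)), 915, 900.0, 30000.0, {}),
    ("Ethyl pentanoate", ((29, 200), (57, 450), (85, 999), (88, 520), (101, 130)), 948, 12.0, 5.0, {"Own": 1.40}),
    ("Ethyl hexanoate", ((43, 420), (60, 230), (88, 999), (99, 510), (115, 130)), 1032, 310.0, 14.0, {"Own": 0.65}),
    ("Hexyl acetate", ((43, 999), (56, 780), (61, 250), (84, 420), (101, 60)), 1068, 28.0, 670.0, {"Own": 1.50}),
    ("Limonene", ((68, 999), (79, 310), (93, 870), (121, 330), (136, 280)), 1098, 40.0, 15.0, {}),
    (
        "Linalool",
        ((41, 600), (55, 450), (71, 999), (80, 300), (93, 800), (121, 150)),
        1125,
        10.9,
        25.2,
        {"Own": 0.55, "1103P": 1.43, "SO4": 0.90},
    ),
    ("Nonanal", ((41, 720), (57, 999), (70, 450), (98, 300), (114, 90)), 1158, 25.0, 1.0, {"Own": 1.50}),
    ("Ethyl octanoate", ((57, 330), (70, 260), (88, 999), (101, 560), (127, 210)), 1195, 580.0, 580.0, {}),
    ("2-Phenylethanol", ((51, 90), (65, 220), (91, 999), (92, 680), (122, 480)), 1228, 14000.0, 14000.0, {}),
    ("Methyl salicylate", ((65, 180), (92, 540), (120, 999), (121, 350), (152, 470)), 1258, 8.0, 40.0, {"Own": 0.60}),
    ("Methyl octanoate", ((55, 230), (74, 999), (87, 540), (127, 150), (158, 60)), 1290, 6.5, 200.0, {"Own": 1.45}),
    ("Ethyl nonanoate", ((70, 240), (88, 999), (101, 490), (141, 180), (186, 50)), 1322, 8.0, 850.0, {"Own": 0.60}),
    ("Vitispirane", ((91, 280), (107, 340), (121, 230), (177, 999), (192, 620)), 1360, 55.0, 800.0, {}),
    ("Ethyl decanoate", ((70, 260), (88, 999), (101, 530), (155, 190), (200, 60)), 1395, 210.0, 200.0, {}),
    (
        "Diethyl succinate",
        ((55, 310), (73, 250), (101, 999), (129, 780), (174, 40)),
        1430,
        1500.0,
        200000.0,
        {"Own": 1.45},
    ),
    ("Citronellol", ((41, 740), (69, 999), (81, 390), (95, 450), (123, 160)), 1466, 18.0, 100.0, {}),
    ("Nerol oxide", ((68, 999), (83, 540), (93, 380), (139, 250), (154, 120)), 1505, 9.0, None, {"Own": 0.65, "3309C": 0.85}),
    ("TDN", ((115, 280), (128, 190), (142, 720), (157, 999), (172, 560)), 1545, 12.5, 2.0, {"Own": 1.35, "RDI": 1.10}),
    ("Geranylacetone", ((43, 999), (69, 510), (107, 290), (136, 220), (151, 140)), 1585, 6.0, 60.0, {}),
    ("Ethyl dodecanoate", ((70, 270), (88, 999), (101, 520), (183, 130), (228, 40)), 1640, 30.0, 1500.0, {}),
    ("gamma-Nonalactone", ((41, 310), (57, 220), (85, 999), (100, 130), (114, 60)), 1692, 14.0, 30.0, {"Own": 1.55}),
    (
        "beta-Damascenone",
        ((41, 350), (69, 999), (105, 250), (121, 740), (190, 300)),
        1824,
        8.59,
        4.5,
        {"Own": 1.105, "RDI": 1.10},
    ),
]

# Compounds with >= 25 % planted rootstock shifts (the "strong" effects the
# differential stage is expected to recover).
PLANTED_STRONG = tuple(
    name
    for name, _, _, _, _, mult in NAMED_COMPOUNDS
    if any(abs(v - 1.0) >= 0.25 for k, v in mult.items() if k in ROOTSTOCKS)
)

# All compounds carrying any non-unit effect (true alternatives for FDR
# accounting; includes the subtle beta-damascenone shift).
PLANTED_ANY = tuple(name for name, _, _, _, _, mult in NAMED_COMPOUNDS if mult)

# RI-displaced doppelgänger library entries: same spectrum as a real study
# compound but a literature RI shifted far beyond the acceptance tolerance.
_DECOYS: list[tuple[str, str, float]] = [
    ("Nerol", "Linalool", 1185),
    ("Methyl heptanoate", "Ethyl hexanoate", 972),
    ("alpha-Ionone", "beta-Damascenone", 1884),
    ("1,2-Dihydronaphthalene", "TDN", 1485),
    ("Terpinolene", "Limonene", 1038),
    ("Methyl nonanoate", "Ethyl octanoate", 1255),
    ("Geraniol", "Citronellol", 1526),
    ("Decanal", "Nonanal", 1218),
    ("(Z)-3-Hexenyl acetate", "Hexyl acetate", 1008),
    ("2-Methylbutyl acetate", "Isoamyl acetate", 938),
]

_LIBRARY_EXTRAS: list[tuple[str, tuple[tuple[int, int], ...], float]] = [
    ("Furfural", ((39, 420), (95, 950), (96, 999)), 828),
    ("Benzaldehyde", ((51, 380), (77, 850), (105, 970), (106, 999)), 952),
    ("Guaiacol", ((81, 420), (109, 999), (124, 850)), 1859),
    ("Octanoic acid", ((60, 999), (73, 740), (101, 280), (115, 160)), 2060),
    ("Ethyl cinnamate", ((77, 280), (103, 540), (131, 999), (176, 390)), 2130),
    ("Eugenol", ((77, 200), (103, 240), (131, 310), (149, 420), (164, 999)), 2160),
]

# fixed small offsets between the simulated column RI and the "literature" RI,
# cycled over the named compounds; beta-damascenone gets +8 explicitly so the
# library carries 1832 against a true column RI of 1824.
_RI_LIT_OFFSETS = (3, -5, 8, 0, -7, 5, -2, 9, -4, 6)


def default_ladder() -> dict[int, float]:
    """C7–C30 alkane ladder with a gently curved temperature-programmed
    spacing over a ~37-minute run."""
    out = {}
    for n in range(7, 31):
        k = n - 7
        out[n] = round(1.60 + 1.62 * k - 0.0045 * k * k, 4)
    return out


def default_design(year: int = 2018, vines: int = 2, injections: int = 2) -> list[SampleMeta]:
    """Full factorial rootstock × irrigation design with ``vines`` biological
    replicates per cell, each injected ``injections`` times."""
    design = []
    for rs in ROOTSTOCKS:
        for irr in IRRIGATIONS:
            for vine in range(1, vines + 1):
                sid = f"{rs}_{irr}_v{vine}"
                for inj in range(1, injections + 1):
                    design.append(SampleMeta(sid, rs, irr, year, vine, inj))
    return design


def _unknown_compounds(cv: float) -> list[CompoundSpec]:
    """36 deterministic 'unknown' volatiles (not in the spectral library, no
    treatment effects) filling the RI axis between the named compounds."""
    rng = np.random.default_rng(777)  # fixed: structural, independent of study seed
    named_ris = [ri for _, _, ri, _, _, _ in NAMED_COMPOUNDS] + [
        s.true_ri for s in INTERNAL_STANDARDS.values()
    ]
    ris: list[float] = []
    c = 772.0
    while len(ris) < 36 and c < 2950:
        if all(abs(c - r) >= 16 for r in named_ris + ris):
            ris.append(c)
        c += 23.0
    if len(ris) < 36:
        raise RuntimeError("could not place 36 unknown compounds on the RI axis")
    frag_pool = np.array([41, 43, 55, 57, 67, 69, 71, 79, 81, 83, 91, 93, 95, 105, 107, 109, 119, 121, 133, 147])
    out = []
    for i, ri in enumerate(ris):
        n_ions = int(rng.integers(4, 8))
        ions = rng.choice(frag_pool, size=n_ions, replace=False)
        mol = int(rng.integers(110, 240))
        ints = np.concatenate([[999.0], np.round(rng.uniform(80, 700, size=n_ions - 1), 0), [float(rng.integers(20, 200))]])
        mzs = np.concatenate([ions, [mol]])
        order = np.argsort(mzs)
        spectrum = tuple((int(m), float(v)) for m, v in zip(mzs[order], ints[order]))
        base = float(np.round(10 ** rng.uniform(1.0, 2.3), 1))
        out.append(
            CompoundSpec(
                name=f"Unknown_{i + 1:02d}",
                spectrum=spectrum,
                true_ri=float(ri),
                base_conc=base,
                cv=cv,
            )
        )
    return out


def default_study_recipe(
    seed: int = 0,
    planted: bool = True,
    cv: float = 0.15,
    noise_floor: float = 3.0,
    year: int = 2018,
    vines: int = 2,
    injections: int = 2,
) -> StudyRecipe:
    """The built-in study: 4 rootstocks × 3 irrigation regimes × ``vines``
    biological replicates, duplicate injections, 60 compounds (24 wine
    volatiles with library entries + 36 unknowns), three internal standards at
    50/100/50 ppb and a C7–C30 ladder.

    With ``planted=True`` twelve compounds carry ≥ 25 % rootstock shifts (plus
    the subtle ~10 % beta-damascenone contrast); ``planted=False`` yields a
    null study with identical structure and no treatment effects.
    """
    compounds = []
    for name, spectrum, ri, base, thr, mult in NAMED_COMPOUNDS:
        compounds.append(
            CompoundSpec(
                name=name,
                spectrum=spectrum,
                true_ri=float(ri),
                base_conc=base,
                effect_multiplier=dict(mult) if planted else {},
                cv=cv,
                odor_threshold=thr,
            )
        )
    compounds.extend(_unknown_compounds(cv))
    return StudyRecipe(
        design=default_design(year=year, vines=vines, injections=injections),
        compounds=compounds,
        internal_standards=[("2-Octanol", 50.0), ("4-Methyl-2-pentanol", 100.0), ("3-Octanone", 50.0)],
        ladder=default_ladder(),
        rt_drift_sd=0.01,
        noise_floor=noise_floor,
        scan_hz=120.0,
        rt_range=(0.5, 39.5),
        peak_sigma_s=2.5,
        seed=seed,
    )


def default_library(include_decoys: bool = True) -> list[LibrarySpectrum]:
    """Reference library: the 24 named wine volatiles (literature RIs offset a
    few units from the simulated column), optionally 10 RI-displaced decoys,
    and 6 compounds not present in the built-in study (40 records total)."""
    specs: list[LibrarySpectrum] = []
    by_name: dict[str, tuple] = {t[0]: t for t in NAMED_COMPOUNDS}
    for i, (name, spectrum, ri, _, _, _) in enumerate(NAMED_COMPOUNDS):
        if name == "beta-Damascenone":
            ri_lit = 1832.0
        else:
            ri_lit = float(ri + _RI_LIT_OFFSETS[i % len(_RI_LIT_OFFSETS)])
        specs.append(LibrarySpectrum(name, spectrum, ri_lit))
    if include_decoys:
        for decoy_name, partner, ri_lit in _DECOYS:
            spectrum = by_name[partner][1]
            specs.append(LibrarySpectrum(decoy_name, spectrum, float(ri_lit)))
    for name, spectrum, ri in _LIBRARY_EXTRAS:
        specs.append(LibrarySpectrum(name, spectrum, float(ri)))
    return specs


def decoy_names() -> tuple[str, ...]:
    return tuple(name for name, _, _ in _DECOYS)


def default_thresholds() -> pd.DataFrame:
    """Odor-threshold table (compound, threshold_ugL) for the built-in study."""
    rows = [
        {"compound": name, "threshold_ugL": thr}
        for name, _, _, _, thr, _ in NAMED_COMPOUNDS
        if thr is not None
    ]
    return pd.DataFrame(rows)
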