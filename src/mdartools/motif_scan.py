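"""Sequence-feature detection for MDAR subcellular-class assignment.

Detects every signal the classifier consumes:

* C-terminal PTS1-like tripeptides (canonical SKL, a curated list of
  experimentally supported variants, and an optional loose pattern tier);
* transmembrane spans by Kyte-Doolittle mean hydropathy in a sliding window;
* the membrane peroxisome-targeting signal (mPTS): a C-terminal TM span
  followed by a cluster of basic residues such as RRRRRW;
* N-terminal extensions relative to a cytosolic-core reference row of the
  family alignment, scored by a transit-peptide composition heuristic;
* conservation of the catalytic residues (Arg320/Tyr349 in rice MDAR
  numbering) — sequences failing this are "MDAR-like", not true MDARs;
* atypical length and duplicated catalytic cores.

The organellar-targeting heuristic is a deliberately simple, documented
stand-in for dedicated transit-peptide predictors; every threshold is
configurable through :class:`ScanConfig`.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .sequence_io import AlignedSet, GAP, ProteinRecord

#: Kyte-Doolittle hydropathy index; 'X' (unknown residue) scores 0.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

CANONICAL_PTS1 = "SKL"
#: PTS1-like tripeptides observed on cytosolic/peroxisomal (class III) MDARs.
DEFAULT_PTS1_LIST = (
    "AKI", "AKV", "ASL", "SNL", "SKV", "SKI", "SKF", "SRI", "CKM", "CKI",
)
PTS1_PATTERN = re.compile(r"^[ASC][KRNS][LIVMF]$")

#: Catalytic residues essential for MDAR activity, in ungapped reference
#: coordinates (rice OsaMDAR3 numbering).
DEFAULT_CATALYTIC = {"R320": (320, "R"), "Y349": (349, "Y")}


@dataclass(frozen=True)
class ScanConfig:
    """All tunable thresholds of the feature scanners."""

    pts1_list: tuple[str, ...] = DEFAULT_PTS1_LIST
    pattern_enabled: bool = False
    tm_window: int = 19
    tm_threshold: float = 1.6
    cterm_margin: int = 40
    tail_window: int = 10
    min_basic: int = 4
    cluster_window: int = 6
    min_extension: int = 30
    head_len: int = 50
    organellar_threshold: float = 0.05
    typical_length_range: tuple[int, int] = (400, 552)
    catalytic_positions: dict = field(
        default_factory=lambda: dict(DEFAULT_CATALYTIC)
    )
    catalytic_context_motif: Optional[str] = None

    @classmethod
    def from_file(cls, path: str) -> "ScanConfig":
        """Load overrides from a simple ``key = value`` file."""
        cfg = cls()
        overrides = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                key, val = key.strip(), val.strip()
                if key == "pts1_list":
                    overrides[key] = tuple(v.strip() for v in val.split(","))
                elif key == "pattern_enabled":
                    overrides[key] = val.lower() in ("1", "true", "yes")
                elif key in ("tm_threshold", "organellar_threshold"):
                    overrides[key] = float(val)
                elif key == "typical_length_range":
                    lo, hi = val.split(",")
                    overrides[key] = (int(lo), int(hi))
                elif key == "catalytic_context_motif":
                    overrides[key] = val
                elif hasattr(cfg, key):
                    overrides[key] = int(val)
                else:
                    raise ValueError(f"unknown config key '{key}'")
        return replace(cfg, **overrides)


@dataclass(frozen=True)
class Pts1Result:
    present: bool
    tripeptide: str
    tier: str  # canonical | listed | pattern | none


@dataclass(frozen=True)
class TmSpan:
    start: int  # 1-based inclusive
    end: int
    mean_hydropathy: float


@dataclass(frozen=True)
class MptsResult:
    has_cterm_tm: bool
    tm: Optional[TmSpan]
    basic_cluster: bool
    cluster_seq: str


@dataclass(frozen=True)
class NtermExtension:
    length: int
    extension_seq: str
    organellar_score: float
    organellar: bool


@dataclass(frozen=True)
class CatalyticCheck:
    ok: bool
    residues_found: dict[str, str]


@dataclass(frozen=True)
class AtypicalFlags:
    length_atypical: bool
    dual_catalytic_core: bool
    length: int


def scan_pts1(
    record: ProteinRecord,
    pts1_list: tuple[str, ...] = DEFAULT_PTS1_LIST,
    enable_pattern: bool = False,
) -> Pts1Result:
    """Classify the C-terminal tripeptide into a PTS1 tier.

    Tiers, in precedence order: ``canonical`` (SKL), ``listed`` (curated
    variants seen on class III MDARs), ``pattern`` (loose [ASC][KRNS][LIVMF],
    off by default), ``none``. Only the final three residues matter.
    """
    if len(record.sequence) < 3:
        raise ValueError(f"record '{record.id}': sequence shorter than 3 residues")
    tri = record.sequence[-3:]
    if tri == CANONICAL_PTS1:
        return Pts1Result(True, tri, "canonical")
    if tri in pts1_list:
        return Pts1Result(True, tri, "listed")
    if enable_pattern and PTS1_PATTERN.match(tri):
        return Pts1Result(True, tri, "pattern")
    return Pts1Result(False, "", "none")


def hydropathy_profile(sequence: str, window: int = 19) -> np.ndarray:
    """Sliding-window mean Kyte-Doolittle hydropathy, NaN within half a
    window of either end."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    n = len(sequence)
    if window > n:
        raise ValueError(f"window {window} exceeds sequence length {n}")
    values = np.array([KYTE_DOOLITTLE[a] for a in sequence])
    kernel = np.ones(window) / window
    means = np.convolve(values, kernel, mode="valid")
    profile = np.full(n, np.nan)
    half = window // 2
    profile[half : n - half] = means
    return profile


def detect_tm(
    record: ProteinRecord, window: int = 19, threshold: float = 1.6
) -> list[TmSpan]:
    """Find candidate transmembrane spans.

    Maximal runs of window centers with mean hydropathy >= ``threshold``,
    merged when separated by fewer than 3 positions. Each span covers the
    full windows of its run (first center - window//2 to last center +
    window//2, 1-based).
    """
    n = len(record.sequence)
    if n < window:
        return []
    profile = hydropathy_profile(record.sequence, window)
    centers = np.flatnonzero(~np.isnan(profile) & (profile >= threshold))
    if centers.size == 0:
        return []
    runs: list[list[int]] = [[int(centers[0]), int(centers[0])]]
    for c in centers[1:]:
        if c - runs[-1][1] < 3:  # gap of < 3 positions: merge
            runs[-1][1] = int(c)
        else:
            runs.append([int(c), int(c)])
    half = window // 2
    spans = []
    for lo, hi in runs:
        seg = profile[lo : hi + 1]
        spans.append(
            TmSpan(
                start=lo - half + 1,
                end=hi + half + 1,
                mean_hydropathy=float(np.nanmean(seg)),
            )
        )
    return sorted(spans, key=lambda s: s.start)


def scan_mpts(
    record: ProteinRecord,
    tm_spans: list[TmSpan],
    tail_window: int = 10,
    min_basic: int = 4,
    cterm_margin: int = 40,
    cluster_window: int = 6,
) -> MptsResult:
    """Test for a membrane PTS: C-terminal TM span plus adjacent basic cluster.

    The cluster search begins half a hydropathy window before the detected
    span end, because window smoothing extends detected spans past the
    physical TM terminus; requiring the cluster strictly after the smoothed
    end would miss genuinely adjacent clusters like RRRRRW.
    """
    n = len(record.sequence)
    cterm = [s for s in tm_spans if s.end >= n - cterm_margin + 1]
    if not cterm:
        return MptsResult(False, None, False, "")
    span = max(cterm, key=lambda s: s.end)
    half = (span.end - span.start) // 2 if span.end - span.start < 18 else 9
    lo = max(span.start, span.end - half)  # 1-based start of search region
    hi = min(span.end + tail_window, n)
    best: tuple[int, int] = (0, -1)  # (basic count, window start)
    for s in range(lo, hi - cluster_window + 2):
        win = record.sequence[s - 1 : s - 1 + cluster_window]
        count = sum(1 for a in win if a in "KR")
        if count >= best[0]:  # ties resolved toward the later window
            best = (count, s)
    if best[0] >= min_basic:
        s = best[1]
        return MptsResult(
            True, span, True, record.sequence[s - 1 : s - 1 + cluster_window]
        )
    return MptsResult(True, span, False, "")


def predict_organellar(
    extension_seq: str,
    head_len: int = 50,
    threshold: float = 0.05,
) -> tuple[float, bool]:
    """Transit-peptide composition heuristic.

    Chloroplast/mitochondrial presequences are enriched in serine and
    arginine and depleted in acidic residues, so the score is
    freq(S) + freq(R) - freq(D) - freq(E) over the first ``head_len``
    residues. This is a documented, replaceable stand-in for dedicated
    targeting predictors, not a reimplementation of one.
    """
    if not extension_seq:
        raise ValueError("empty extension sequence")
    head = extension_seq[:head_len]
    n = len(head)
    score = (
        head.count("S") + head.count("R") - head.count("D") - head.count("E")
    ) / n
    return score, score > threshold


def detect_nterm_extension(
    aligned: AlignedSet,
    ref_id: str,
    query_id: str,
    min_extension: int = 30,
    head_len: int = 50,
    organellar_threshold: float = 0.05,
) -> NtermExtension:
    """Measure the query's N-terminal extension relative to a cytosolic-core
    reference row and score it for organellar targeting.

    The extension is every non-gap query residue in alignment columns
    strictly before the reference row's first non-gap column. Extensions
    shorter than ``min_extension`` are never called organellar.
    """
    ref_row = aligned.row(ref_id)
    query_row = aligned.row(query_id)
    ref_start = next(
        (i for i, ch in enumerate(ref_row) if ch != GAP), len(ref_row)
    )
    ext = query_row[:ref_start].replace(GAP, "")
    if len(ext) >= min_extension:
        score, organellar = predict_organellar(ext, head_len, organellar_threshold)
    elif ext:
        score, _ = predict_organellar(ext, head_len, organellar_threshold)
        organellar = False
    else:
        score, organellar = 0.0, False
    return NtermExtension(len(ext), ext, score, organellar)


def check_catalytic(
    aligned: AlignedSet,
    ref_id: str,
    query_id: str,
    ref_positions: Optional[dict[str, tuple[int, str]]] = None,
) -> CatalyticCheck:
    """Check conservation of catalytic residues via the family alignment.

    ``ref_positions`` maps labels (e.g. "R320") to 1-based ungapped reference
    positions and expected residues. For each, the alignment column holding
    that reference residue is located and the query residue there reported
    ('-' for a deletion). ``ok`` requires every position to match.
    """
    if ref_positions is None:
        ref_positions = DEFAULT_CATALYTIC
    ref_row = aligned.row(ref_id)
    query_row = aligned.row(query_id)
    # map ungapped reference position -> alignment column
    cols: list[int] = []
    for i, ch in enumerate(ref_row):
        if ch != GAP:
            cols.append(i)
    found: dict[str, str] = {}
    ok = True
    for label, (pos, expected) in sorted(ref_positions.items()):
        if pos > len(cols):
            raise ValueError(
                f"reference '{ref_id}' has only {len(cols)} residues, "
                f"cannot locate {label}"
            )
        residue = query_row[cols[pos - 1]]
        found[label] = residue
        if residue != expected:
            ok = False
    return CatalyticCheck(ok, found)


def detect_atypical(
    record: ProteinRecord,
    typical_range: tuple[int, int] = (400, 552),
    catalytic_context_motif: Optional[str] = None,
    min_separation: int = 300,
) -> AtypicalFlags:
    """Flag atypical length and duplicated catalytic cores.

    Most plant MDARs fall in the 400-552 residue range; rare grass isoforms
    near twice that length carry two complete oxidoreductase cores. The dual
    core is detected as >= 2 non-overlapping matches of a catalytic-context
    motif separated by at least ``min_separation`` residues (a proxy for a
    domain-level search).
    """
    n = len(record.sequence)
    length_atypical = not (typical_range[0] <= n <= typical_range[1])
    dual = False
    if catalytic_context_motif:
        starts = [
            m.start() for m in re.finditer(catalytic_context_motif, record.sequence)
        ]
        dual = any(
            b - a >= min_separation for a in starts for b in starts if b > a
        )
    return AtypicalFlags(length_atypical, dual, n)
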