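"""Synthetic MDAR-like protein families with planted targeting signals.

Generates a family that exercises every pipeline stage without any database
download: a single ancestral catalytic core (fixed Arg/Tyr at the reference
catalytic positions) diverges first into per-class lineages and then into
per-species copies by seeded point substitutions, and each class lineage is
decorated with its diagnostic signal:

* class I       — a serine/arginine-rich 60-residue N-terminal extension;
* class II      — a 21-residue hydrophobic C-terminal span plus the basic
                  cluster RRRRRW (optionally omitted to emulate the
                  grass-type subclass);
* class III_pts1 — a PTS1-like tripeptide appended to the C-terminus;
* class III_cyto — the bare core;
* MDAR_like     — the core with the catalytic arginine substituted.

Substitutions never touch planted signal residues or the catalytic
positions, and the ancestral core is resampled wherever a hydropathy window
approaches the transmembrane detection threshold, so signal detection has
no false positives by construction. Because decorations live in dedicated
alignment blocks and indels are off by default, the true alignment is known
exactly and is emitted alongside the FASTA and a truth table.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motif_scan import (
    CANONICAL_PTS1,
    DEFAULT_PTS1_LIST,
    KYTE_DOOLITTLE,
    PTS1_PATTERN,
)
from .sequence_io import AlignedSet, GAP, ProteinRecord
from .genetics import SegregationModel, expected_freqs

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
CLASS_LABELS = ("I", "II", "III_pts1", "III_cyto", "MDAR_like")
REF_ID = "REF_CYTO"

EXTENSION_LEN = 60
TM_LEN = 21
TM_RESIDUES = "ILVF"
BASIC_CLUSTER = "RRRRRW"
NO_CLUSTER_TAIL = "SSSSSS"  # grass-type class II tail, same block width

DEFAULT_CLASSES = {"I": 1, "II": 1, "III_pts1": 1, "III_cyto": 2, "MDAR_like": 0}


@dataclass(frozen=True)
class FamilySpec:
    """Study conditions for one synthetic family."""

    n_species: int = 5
    classes_per_species: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASSES)
    )
    core_length: int = 435
    mutation_rate: float = 0.05  # substitutions per site per lineage step
    indels: bool = False
    seed: int = 1
    catalytic_r: int = 320  # 1-based core positions, rice MDAR numbering
    catalytic_y: int = 349
    pts1_list: tuple[str, ...] = DEFAULT_PTS1_LIST
    class_ii_basic_cluster: bool = True

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not 400 <= self.core_length <= 552:
            raise ValueError("core_length must lie in the typical range 400-552")
        if not 0.0 <= self.mutation_rate < 0.3:
            raise ValueError("mutation_rate must lie in [0, 0.3)")
        unknown = set(self.classes_per_species) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")
        if any(v < 0 for v in self.classes_per_species.values()):
            raise ValueError("class counts must be >= 0")
        if max(self.catalytic_r, self.catalytic_y) > self.core_length:
            raise ValueError("catalytic positions exceed core length")
        if self.indels:
            raise NotImplementedError(
                "indel mode requires an externally supplied alignment"
            )


def _window_means(values: np.ndarray, window: int = 19) -> np.ndarray:
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="valid")


def _sample_core(rng: np.random.Generator, spec: FamilySpec) -> str:
    """Ancestral core: uniform residues, fixed catalytic Arg/Tyr, and no
    hydropathy window anywhere near the TM detection threshold.

    Windows are resampled until every 19-window mean stays below 1.1 — a
    margin comfortably under the 1.6 detection threshold so that later
    point substitutions cannot create spurious transmembrane calls.
    """
    n = spec.core_length
    protected = {spec.catalytic_r - 1, spec.catalytic_y - 1}
    seq = rng.choice(list(AMINO_ACIDS), size=n)
    seq[spec.catalytic_r - 1] = "R"
    seq[spec.catalytic_y - 1] = "Y"
    kd = np.vectorize(KYTE_DOOLITTLE.get)
    for _ in range(500):
        means = _window_means(kd(seq).astype(float))
        bad = np.flatnonzero(means >= 1.1)
        if bad.size == 0:
            break
        for start in bad:
            for pos in range(start, start + 19):
                if pos not in protected:
                    seq[pos] = rng.choice(list(AMINO_ACIDS))
            seq[spec.catalytic_r - 1] = "R"
            seq[spec.catalytic_y - 1] = "Y"
    else:
        raise RuntimeError("could not sample a TM-free ancestral core")
    # keep the bare core's C-terminus free of accidental PTS1-like signals
    while (
        "".join(seq[-3:]) == CANONICAL_PTS1
        or "".join(seq[-3:]) in spec.pts1_list
        or PTS1_PATTERN.match("".join(seq[-3:]))
    ):
        seq[-3:] = rng.choice(list(AMINO_ACIDS), size=3)
    return "".join(seq)


def _mutate(
    rng: np.random.Generator, sequence: str, rate: float, protected: set[int]
) -> str:
    """Point substitutions at ``rate`` per site, sparing protected sites."""
    if rate == 0.0:
        return sequence
    seq = list(sequence)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for pos in hits:
        if int(pos) in protected:
            continue
        current = seq[pos]
        choices = [a for a in AMINO_ACIDS if a != current]
        seq[pos] = choices[rng.integers(0, len(choices))]
    return "".join(seq)


def catalytic_context(core: str, position: int, flank: int = 3) -> str:
    """The 7-residue window centered on a catalytic position of a core —
    usable as the duplicated-core motif for synthetic sequences."""
    return core[position - 1 - flank : position + flank]


def generate_family(
    spec: FamilySpec,
) -> tuple[list[ProteinRecord], AlignedSet, pd.DataFrame]:
    """Generate (records, true alignment, truth table) for one family.

    The alignment coordinate frame is fixed blocks:
    [extension 60 | core | TM 21 | cluster 6 | PTS1 3]; every record fills
    only the blocks its class carries, so ungapping a row recovers its
    sequence exactly. An undecorated, unmutated reference row ``REF_CYTO``
    is always included for extension measurement and catalytic checks.
    Deterministic for a fixed spec (same seed -> byte-identical output).
    """
    rng = np.random.default_rng(spec.seed)
    core0 = _sample_core(rng, spec)
    protected = {spec.catalytic_r - 1, spec.catalytic_y - 1}
    # signal decorations are drawn once per class lineage and never mutated
    ext_probs = np.full(len(AMINO_ACIDS), 0.4 / 18)
    ext_probs[AMINO_ACIDS.index("S")] = 0.3
    ext_probs[AMINO_ACIDS.index("R")] = 0.3
    extension = "".join(
        rng.choice(list(AMINO_ACIDS), size=EXTENSION_LEN, p=ext_probs)
    )
    tm_seq = "".join(rng.choice(list(TM_RESIDUES), size=TM_LEN))
    cluster = BASIC_CLUSTER if spec.class_ii_basic_cluster else NO_CLUSTER_TAIL

    labels_used = [
        lab for lab in CLASS_LABELS if spec.classes_per_species.get(lab, 0) > 0
    ]
    class_ancestors = {
        lab: _mutate(rng, core0, spec.mutation_rate, protected)
        for lab in labels_used
    }
    if "MDAR_like" in class_ancestors:
        seq = list(class_ancestors["MDAR_like"])
        seq[spec.catalytic_r - 1] = "A"  # planted loss of the catalytic Arg
        class_ancestors["MDAR_like"] = "".join(seq)

    records: list[ProteinRecord] = []
    rows: list[tuple[str, str]] = []
    truth_rows: list[dict] = []

    def add_row(rec_id, species, label, core, ext, tm, clus, pts1):
        parts = [
            ext if ext else GAP * EXTENSION_LEN,
            core,
            tm if tm else GAP * TM_LEN,
            clus if clus else GAP * len(BASIC_CLUSTER),
            pts1 if pts1 else GAP * 3,
        ]
        row = "".join(parts)
        rows.append((rec_id, row))
        records.append(
            ProteinRecord(
                rec_id,
                row.replace(GAP, ""),
                species=species,
                lineage="Synthetic",
            )
        )
        truth_rows.append(
            {
                "id": rec_id,
                "species": species,
                "planted_class": label,
                "extension_seq": ext,
                "tm_seq": tm,
                "cluster_seq": clus,
                "pts1_tripeptide": pts1,
                "catalytic_positions": f"{spec.catalytic_r},{spec.catalytic_y}",
            }
        )

    add_row(REF_ID, "reference", "III_cyto", core0, "", "", "", "")
    for si in range(1, spec.n_species + 1):
        species = f"Species{si:02d}"
        for label in labels_used:
            for k in range(spec.classes_per_species[label]):
                rec_id = f"sp{si:02d}_{label}_{k + 1}"
                core = _mutate(
                    rng, class_ancestors[label], spec.mutation_rate, protected
                )
                ext = tm = clus = pts1 = ""
                if label == "I":
                    ext = extension
                elif label == "II":
                    tm, clus = tm_seq, cluster
                elif label == "III_pts1":
                    pts1 = spec.pts1_list[rng.integers(0, len(spec.pts1_list))]
                add_row(rec_id, species, label, core, ext, tm, clus, pts1)

    aligned = AlignedSet(rows)
    truth = pd.DataFrame(truth_rows)
    return records, aligned, truth


def predicted_label(classification) -> str:
    """Map a pipeline classification back onto the generator's class labels."""
    cls = classification.primary_class
    if cls == "MDAR-like":
        return "MDAR_like"
    if cls in ("I", "II"):
        return cls
    if "dual_targeting_pts1" in classification.subclass_flags:
        return "III_pts1"
    return "III_cyto"


def recovery_accuracy(classifications, truth: pd.DataFrame) -> float:
    """Fraction of sequences whose planted class the pipeline recovered."""
    planted = dict(zip(truth["id"], truth["planted_class"]))
    by_id = {c.id: c for c in classifications}
    hits = sum(
        1
        for rec_id, label in planted.items()
        if predicted_label(by_id[rec_id]) == label
    )
    return hits / len(planted)


def species_map_from_truth(truth: pd.DataFrame) -> dict:
    return {
        row["id"]: (row["species"], "Synthetic") for _, row in truth.iterrows()
    }


def generate_genotype_counts(
    model: SegregationModel, n: int, seed: int
) -> dict:
    """Seeded multinomial draw of ``n`` surviving progeny from the model's
    expected genotype distribution."""
    if n < 1:
        raise ValueError("n must be >= 1")
    freqs = expected_freqs(model)
    genotypes = sorted(freqs)
    probs = np.array([freqs[g] for g in genotypes])
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, probs)
    return {g: int(c) for g, c in zip(genotypes, counts)}
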