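"""Rule-based assignment of MDAR sequences to subcellular-targeting classes.

Classes follow the standard three-way division of the plant MDAR family:

* class I — chloroplastic/mitochondrial isoforms, recognized by an
  organellar N-terminal extension;
* class II — peroxisomal membrane isoforms, recognized by a C-terminal
  transmembrane span (the mPTS), usually followed by a basic cluster;
* class III — cytosolic/peroxisomal isoforms; those with a PTS1-like
  tripeptide can dual-target the peroxisomal matrix, those without are
  cytosol-specific.

Sequences lacking the catalytic arginine/tyrosine are set aside as
"MDAR-like" and never classified. Signals take precedence over the tree:
the phylogeny, when supplied, only corroborates (clade_class) or contests
(conflict flag) the signal-based call, mirroring how targeting evidence and
phylogeny are combined in practice.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from ._tree import Tree
from .motif_scan import (
    AtypicalFlags,
    CatalyticCheck,
    MptsResult,
    NtermExtension,
    Pts1Result,
    ScanConfig,
    TmSpan,
    check_catalytic,
    detect_atypical,
    detect_nterm_extension,
    detect_tm,
    scan_mpts,
    scan_pts1,
)
from .sequence_io import AlignedSet, ProteinRecord

logger = logging.getLogger(__name__)

CLASS_I = "I"
CLASS_II = "II"
CLASS_III = "III"
MDAR_LIKE = "MDAR-like"


@dataclass(frozen=True)
class SignalAnnotation:
    """The full feature vector for one sequence."""

    record: ProteinRecord
    catalytic: CatalyticCheck
    pts1: Pts1Result
    mpts: MptsResult
    nterm: NtermExtension
    atypical: AtypicalFlags
    tm_spans: tuple[TmSpan, ...] = ()


@dataclass
class Classification:
    id: str
    primary_class: str
    subclass_flags: frozenset[str]
    evidence: list[str]
    signals: SignalAnnotation
    clade_class: Optional[str] = None


def compute_signals(
    record: ProteinRecord,
    aligned: AlignedSet,
    ref_id: str,
    config: Optional[ScanConfig] = None,
) -> SignalAnnotation:
    """Run every feature scanner for one record against the family alignment."""
    cfg = config or ScanConfig()
    catalytic = check_catalytic(aligned, ref_id, record.id, cfg.catalytic_positions)
    pts1 = scan_pts1(record, cfg.pts1_list, cfg.pattern_enabled)
    tm_spans = detect_tm(record, cfg.tm_window, cfg.tm_threshold)
    mpts = scan_mpts(
        record,
        tm_spans,
        cfg.tail_window,
        cfg.min_basic,
        cfg.cterm_margin,
        cfg.cluster_window,
    )
    nterm = detect_nterm_extension(
        aligned,
        ref_id,
        record.id,
        cfg.min_extension,
        cfg.head_len,
        cfg.organellar_threshold,
    )
    atypical = detect_atypical(
        record, cfg.typical_length_range, cfg.catalytic_context_motif
    )
    return SignalAnnotation(
        record, catalytic, pts1, mpts, nterm, atypical, tuple(tm_spans)
    )


def classify_sequence(signals: SignalAnnotation) -> Classification:
    """Assign one sequence to a class from its signals alone.

    Rule order: failed catalytic check -> MDAR-like; C-terminal TM -> class
    II (flagged when the basic cluster is missing); organellar extension
    without PTS1 -> class I; everything else -> class III, split into
    PTS1-bearing (dual-targeting) and cytosol-specific. An organellar
    extension co-occurring with a PTS1 is a genuine ambiguity and is kept as
    class III with a conflict flag rather than silently resolved.
    """
    for name in ("catalytic", "pts1", "mpts", "nterm", "atypical"):
        if getattr(signals, name) is None:
            raise ValueError(f"missing signal component '{name}'")
    flags: set[str] = set()
    evidence: list[str] = []
    atyp = signals.atypical
    if atyp.length_atypical:
        flags.add("atypical_length")
    if atyp.dual_catalytic_core:
        flags.add("dual_core")

    if not signals.catalytic.ok:
        missing = {
            k: v
            for k, v in signals.catalytic.residues_found.items()
        }
        evidence.append(f"catalytic_failure:{sorted(missing.items())}")
        cls = MDAR_LIKE
    elif signals.mpts.has_cterm_tm:
        cls = CLASS_II
        evidence.append("cterm_tm")
        if signals.mpts.basic_cluster:
            evidence.append(f"basic_cluster:{signals.mpts.cluster_seq}")
        else:
            flags.add("tm_no_basic_cluster")
            evidence.append("no_basic_cluster")
    elif signals.nterm.organellar and not signals.pts1.present:
        cls = CLASS_I
        evidence.append(
            f"organellar_extension:len={signals.nterm.length},"
            f"score={signals.nterm.organellar_score:.3f}"
        )
    else:
        cls = CLASS_III
        if signals.pts1.present:
            flags.add("dual_targeting_pts1")
            evidence.append(
                f"pts1:{signals.pts1.tripeptide}({signals.pts1.tier})"
            )
            if signals.nterm.organellar:
                # organellar extension AND PTS1: contradictory targeting
                flags.add("conflict")
                evidence.append("organellar_extension_with_pts1")
        else:
            flags.add("cytosol_specific")
            evidence.append("no_targeting_signal")
    result = Classification(
        id=signals.record.id,
        primary_class=cls,
        subclass_flags=frozenset(flags),
        evidence=evidence,
        signals=signals,
    )
    logger.info(
        "%s -> %s %s (%s)",
        result.id,
        cls,
        sorted(flags),
        "; ".join(evidence),
    )
    return result


def _clade_vote(
    tree: Tree, by_id: dict[str, Classification], min_clade: int = 3
) -> None:
    """Attach clade_class from the smallest surrounding clade of >= 3 leaves
    with >= 2 signal-classified (non-MDAR-like) members besides the query.

    The vote is a strict plurality of primary classes; ties leave
    clade_class unset. Disagreement with the signal-based call adds the
    conflict flag but never changes the class.
    """
    # ancestors per leaf in the rooted-at-trifurcation representation
    parents: dict[int, object] = {}
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for child in node.children:
            parents[id(child)] = node
            stack.append(child)
    leaf_nodes = {
        node.name: node for node in tree.root.postorder() if node.is_leaf()
    }
    for leaf_name, leaf in leaf_nodes.items():
        query = by_id[leaf_name]
        if query.primary_class == MDAR_LIKE:
            continue
        node = leaf
        while id(node) in parents or node is tree.root:
            if node is not leaf:
                members = [n for n in node.leaf_names() if n != leaf_name]
                voters = [
                    by_id[n].primary_class
                    for n in members
                    if by_id[n].primary_class != MDAR_LIKE
                ]
                if len(members) + 1 >= 3 and len(voters) >= 2:
                    tally = pd.Series(voters).value_counts()
                    if len(tally) == 1 or tally.iloc[0] > tally.iloc[1]:
                        query.clade_class = tally.index[0]
                        if query.clade_class != query.primary_class:
                            query.subclass_flags = query.subclass_flags | {
                                "conflict"
                            }
                            query.evidence.append(
                                f"clade_disagrees:{query.clade_class}"
                            )
                    break
            if node is tree.root:
                break
            node = parents[id(node)]


def classify_family(
    records: list[ProteinRecord],
    signals_all: list[SignalAnnotation],
    tree: Optional[Tree] = None,
) -> list[Classification]:
    """Classify every record, optionally corroborating with a phylogeny."""
    if len(records) != len(signals_all):
        raise ValueError("one SignalAnnotation required per record")
    ids = {r.id for r in records}
    results = [classify_sequence(sig) for sig in signals_all]
    by_id = {c.id: c for c in results}
    if tree is not None:
        extra = set(tree.leaf_names()) - ids
        if extra:
            raise ValueError(
                f"tree leaves not among records: {sorted(extra)}"
            )
        _clade_vote(tree, by_id)
    return results


def run_pipeline(
    aligned: AlignedSet,
    ref_id: str,
    config: Optional[ScanConfig] = None,
    tree: Optional[Tree] = None,
    species_map: Optional[dict[str, tuple[str, Optional[str]]]] = None,
) -> list[Classification]:
    """Signals + classification for every row of a family alignment.

    The reference row itself is classified too (it is a legitimate
    cytosolic core), so callers may drop it from summaries if they wish.
    """
    records = []
    for rec_id, row in aligned.records:
        seq = row.replace("-", "")
        species, lineage = (None, None)
        if species_map and rec_id in species_map:
            species, lineage = species_map[rec_id]
        records.append(
            ProteinRecord(rec_id, seq, species=species, lineage=lineage)
        )
    signals = [
        compute_signals(rec, aligned, ref_id, config) for rec in records
    ]
    return classify_family(records, signals, tree)


SUMMARY_COLUMNS = ["I", "II", "III", "III_cytosol_specific", "MDAR_like", "total"]


def summarize_counts(
    classifications: list[Classification],
    species_map: dict[str, tuple[str, Optional[str]]],
) -> pd.DataFrame:
    """Per-species isoform counts by class (rows sorted by species name)."""
    if not classifications:
        raise ValueError("no classifications to summarize")
    rows: dict[str, dict[str, int]] = {}
    for c in classifications:
        if c.id not in species_map:
            raise ValueError(f"id '{c.id}' missing from species map")
        species = species_map[c.id][0]
        row = rows.setdefault(
            species, {col: 0 for col in SUMMARY_COLUMNS}
        )
        row["total"] += 1
        if c.primary_class == MDAR_LIKE:
            row["MDAR_like"] += 1
        else:
            row[c.primary_class] += 1
            if "cytosol_specific" in c.subclass_flags:
                row["III_cytosol_specific"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index", columns=SUMMARY_COLUMNS)
    df.index.name = "species"
    return df.sort_index()
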