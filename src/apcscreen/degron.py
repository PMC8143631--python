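"""Short-linear-motif scanning for APC/C degrons and hit-level filtering.

The scanner reports every occurrence (including overlapping and nested
ones) of the destruction-box motifs RxxL and RxxLxxxxN and of the KEN box,
with 1-based inclusive coordinates.  Hits are then scored against a small
alignment of validated degron sequences (position-weight-matrix log-odds,
min-max normalized), annotated with the mean per-residue disorder over
their span, and filtered with the screen's cutoffs:

1. similarity score >= 0.75 (inclusive);
2. consensus class medium or high;
3. disorder score >= 0.4 (inclusive);
4. the degron must be intracellular, on a non-secreted protein.

Degrons function only when accessible, hence the disorder requirement;
the localization requirement reflects that APC/C activity is cytoplasmic
and nuclear.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import AMINO_ACIDS, MOTIF_TEMPLATES

logger = logging.getLogger(__name__)

VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

SIMILARITY_CUTOFF = 0.75
DISORDER_CUTOFF = 0.4
#: consensus class derived from the similarity score (config-overridable)
CONSENSUS_BOUNDS = {"high": 0.9, "medium": 0.75}


@dataclass
class DegronHit:
    """One motif occurrence; ``start``/``end`` are 1-based inclusive."""

    protein: str
    degron_class: str
    start: int
    end: int
    matched_seq: str
    similarity: float | None = None
    consensus_class: str | None = None
    disorder: float | None = None
    intracellular: bool = True
    secreted: bool = False
    nested_in_ext: bool = False
    passes: bool | None = None


HIT_COLUMNS = [
    "protein", "degron_class", "start", "end", "matched_seq",
    "similarity", "consensus_class", "disorder",
    "intracellular", "secreted", "nested_in_ext", "passes",
]


def hits_to_frame(hits: Iterable[DegronHit]) -> pd.DataFrame:
    return pd.DataFrame([vars(h) for h in hits], columns=HIT_COLUMNS)


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


def _class_regex(degron_class: str) -> "re.Pattern[str]":
    """Overlap-reporting regex for a motif class (lookahead + capture).

    Anchored positions are literal residues, so 'X' (unknown) can never
    satisfy them; wildcards match any validated residue including 'X'.
    """
    length, anchors = MOTIF_TEMPLATES[degron_class]
    body = "".join(re.escape(anchors[i]) if i in anchors else "." for i in range(length))
    return re.compile(f"(?=({body}))")


def scan_motifs(
    sequence: str,
    classes: Iterable[str] = ("D_min", "D_ext", "KEN"),
    protein: str = "",
) -> list[DegronHit]:
    """All motif occurrences in ``sequence``, overlapping ones included.

    A window matching the extended D-box is reported as ``D_ext`` and — if
    ``D_min`` is also requested — additionally as a ``D_min`` hit over its
    first four residues, flagged ``nested_in_ext``.
    """
    seq = sequence.upper()
    if not seq:
        return []
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise ValueError(f"non-amino-acid residues in sequence: {sorted(bad)}")
    classes = list(classes)
    unknown = [c for c in classes if c not in MOTIF_TEMPLATES]
    if unknown:
        raise KeyError(f"unknown motif class(es): {unknown}")

    hits: list[DegronHit] = []
    for cls in classes:
        length = MOTIF_TEMPLATES[cls][0]
        for m in _class_regex(cls).finditer(seq):
            i = m.start()
            hits.append(
                DegronHit(
                    protein=protein,
                    degron_class=cls,
                    start=i + 1,
                    end=i + length,
                    matched_seq=m.group(1),
                )
            )
    ext_starts = {h.start for h in hits if h.degron_class == "D_ext"}
    for h in hits:
        if h.degron_class == "D_min" and h.start in ext_starts:
            h.nested_in_ext = True
    hits.sort(key=lambda h: (h.start, h.end, h.degron_class))
    return hits


# ---------------------------------------------------------------------------
# Similarity scoring against a reference-degron alignment
# ---------------------------------------------------------------------------


def load_reference_degrons(path=None) -> dict[str, list[str]]:
    """Reference degron alignments, ``{class: [sequences]}``.

    Without ``path``, loads the packaged default
    (``data/reference_degrons_synthetic.tsv``) — a small, consensus-derived
    synthetic alignment standing in for a curated set of validated
    degrons; substitute your own curated file for production scans.
    """
    if path is None:
        src = resources.files("apcscreen").joinpath("data/reference_degrons_synthetic.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    refs: dict[str, list[str]] = {}
    for cls, grp in df.groupby("degron_class"):
        seqs = [s.upper() for s in grp["sequence"]]
        length = MOTIF_TEMPLATES.get(cls, (len(seqs[0]), {}))[0]
        for s in seqs:
            if len(s) != length:
                raise ValueError(
                    f"reference {cls} sequence {s!r} has length {len(s)}, expected {length}"
                )
        refs[cls] = seqs
    return refs


def _pwm_log_odds(references: Sequence[str]) -> np.ndarray:
    """Per-position log-odds matrix, pseudocount 1, uniform 1/20 background.

    Shape (motif length, 20), columns indexed by :data:`AMINO_ACIDS`.
    """
    length = len(references[0])
    counts = np.ones((length, len(AMINO_ACIDS)))  # pseudocount
    idx = {a: k for k, a in enumerate(AMINO_ACIDS)}
    for seq in references:
        for pos, res in enumerate(seq):
            counts[pos, idx[res]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return np.log(freqs * len(AMINO_ACIDS))


def similarity_score(hit_seq: str, references: Sequence[str]) -> float:
    """PWM log-odds of ``hit_seq`` against the reference alignment, min-max
    normalized so the best-scoring reference sequence maps to 1 and the
    worst possible sequence to 0 (clipped to [0, 1]).

    'X' at a free position contributes the column minimum (worst case).
    """
    refs = list(references)
    if not refs:
        raise ValueError("reference degron set is empty")
    if any(len(r) != len(hit_seq) for r in refs):
        raise ValueError("hit and reference alignment lengths differ")
    lom = _pwm_log_odds(refs)
    idx = {a: k for k, a in enumerate(AMINO_ACIDS)}

    def score(seq: str) -> float:
        total = 0.0
        for pos, res in enumerate(seq):
            total += lom[pos, idx[res]] if res in idx else float(lom[pos].min())
        return total

    s = score(hit_seq)
    s_min = float(lom.min(axis=1).sum())
    s_best = max(score(r) for r in refs)
    if math.isclose(s_best, s_min):
        return 1.0
    return float(np.clip((s - s_min) / (s_best - s_min), 0.0, 1.0))


def consensus_class(
    similarity: float, bounds: Mapping[str, float] = CONSENSUS_BOUNDS
) -> str:
    """Categorical consensus similarity derived from the numeric score."""
    if similarity >= bounds["high"]:
        return "high"
    if similarity >= bounds["medium"]:
        return "medium"
    return "low"


# ---------------------------------------------------------------------------
# Disorder
# ---------------------------------------------------------------------------


def annotate_disorder(hit: DegronHit, disorder_track) -> DegronHit:
    """Fill ``hit.disorder`` with the mean per-residue score over its span.

    ``disorder_track`` is either a 0-based array covering the protein or a
    pandas Series indexed by 1-based residue position.  Missing residues
    are an error.
    """
    if isinstance(disorder_track, pd.Series):
        wanted = list(range(hit.start, hit.end + 1))
        if not set(wanted).issubset(set(disorder_track.index)):
            raise KeyError(
                f"disorder track for {hit.protein or 'protein'} lacks residues "
                f"{hit.start}-{hit.end}"
            )
        values = disorder_track.loc[wanted].to_numpy(dtype=float)
    else:
        track = np.asarray(disorder_track, dtype=float)
        if len(track) < hit.end:
            raise KeyError(
                f"disorder track length {len(track)} does not cover span "
                f"{hit.start}-{hit.end}"
            )
        values = track[hit.start - 1: hit.end]
    if np.isnan(values).any():
        raise KeyError(f"disorder track has missing values in span {hit.start}-{hit.end}")
    return replace(hit, disorder=float(values.mean()))


#: residues statistically enriched in intrinsically disordered regions
_DISORDER_PROMOTING = frozenset("AEGKPQRS")


def disorder_heuristic(sequence: str, window: int = 21) -> np.ndarray:
    """Built-in fallback disorder track: windowed fraction of
    disorder-promoting residues.

    This composition heuristic is NOT equivalent to the precomputed
    predictor tracks the screen's cutoffs were tuned on; use real tracks
    whenever available.
    """
    seq = sequence.upper()
    flags = np.array([1.0 if r in _DISORDER_PROMOTING else 0.0 for r in seq])
    if len(flags) == 0:
        return flags
    half = window // 2
    padded = np.pad(flags, half, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")[: len(flags)]


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_hits(
    hits: Sequence[DegronHit],
    localization: pd.DataFrame | None = None,
    min_similarity: float = SIMILARITY_CUTOFF,
    min_disorder: float = DISORDER_CUTOFF,
    allowed_consensus: Iterable[str] = ("medium", "high"),
) -> list[DegronHit]:
    """Set each hit's localization flags and pass/fail verdict.

    A hit passes iff similarity >= ``min_similarity``, consensus class in
    ``allowed_consensus``, disorder >= ``min_disorder`` (both boundaries
    inclusive), and its protein is intracellular and non-secreted.
    Proteins absent from the localization table are treated as
    intracellular and non-secreted, with a warning.
    """
    allowed = set(allowed_consensus)
    loc: dict[str, tuple[bool, bool]] = {}
    if localization is not None:
        loc = {
            r["protein"]: (bool(r["intracellular"]), bool(r["secreted"]))
            for _, r in localization.iterrows()
        }
    warned: set[str] = set()
    out: list[DegronHit] = []
    for hit in hits:
        if hit.similarity is None or hit.disorder is None:
            raise ValueError("hits must be similarity-scored and disorder-annotated first")
        if localization is not None and hit.protein not in loc and hit.protein not in warned:
            logger.warning(
                "protein %s absent from localization table; assuming intracellular, "
                "non-secreted", hit.protein,
            )
            warned.add(hit.protein)
        intra, secr = loc.get(hit.protein, (True, False))
        cls = hit.consensus_class or consensus_class(hit.similarity)
        out.append(
            replace(
                hit,
                intracellular=intra,
                secreted=secr,
                consensus_class=cls,
                passes=(
                    hit.similarity >= min_similarity
                    and cls in allowed
                    and hit.disorder >= min_disorder
                    and intra
                    and not secr
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Proteome-level convenience
# ---------------------------------------------------------------------------


def scan_proteome(
    sequences: Mapping[str, str],
    disorder_tracks: Mapping[str, object] | None = None,
    localization: pd.DataFrame | None = None,
    classes: Iterable[str] = ("D_min", "D_ext", "KEN"),
    references: Mapping[str, Sequence[str]] | None = None,
    min_similarity: float = SIMILARITY_CUTOFF,
    min_disorder: float = DISORDER_CUTOFF,
) -> pd.DataFrame:
    """Scan, score, annotate, and filter every protein; returns the hit table.

    Proteins without a disorder track fall back to the built-in
    composition heuristic (see :func:`disorder_heuristic`; logged once).
    """
    refs = references if references is not None else load_reference_degrons()
    used_heuristic = False
    all_hits: list[DegronHit] = []
    for name in sorted(sequences):
        seq = sequences[name]
        hits = scan_motifs(seq, classes, protein=name)
        if not hits:
            continue
        if disorder_tracks is not None and name in disorder_tracks:
            track = disorder_tracks[name]
        else:
            track = disorder_heuristic(seq)
            used_heuristic = True
        for h in hits:
            if h.degron_class in refs:
                h.similarity = similarity_score(h.matched_seq, refs[h.degron_class])
            else:
                h.similarity = 0.0
            h.consensus_class = consensus_class(h.similarity)
            all_hits.append(annotate_disorder(h, track))
    if used_heuristic:
        logger.warning(
            "disorder tracks missing for some proteins; used the built-in "
            "composition heuristic, which is not equivalent to a trained predictor"
        )
    filtered = filter_hits(
        all_hits, localization, min_similarity=min_similarity, min_disorder=min_disorder
    )
    return hits_to_frame(filtered)
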