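"""PSM-level filtering, protein inference, and relative-abundance rollup.

The chain turns a PSM table (one row per peptide-spectrum match, with
per-channel TMT reporter signal-to-noise) into one relative-abundance (RA)
vector per protein:

1. exclude PSMs whose summed S/N across channels is below 100 (an
   instrument-scale quality floor);
2. column-normalize every channel so all channel totals are equal
   (equal-loading correction);
3. score each protein as the product of its peptides' posterior
   probabilities, and control protein-level FDR with the picked
   target-decoy procedure at 1%;
4. collapse accepted identifications to a minimum protein set by maximum
   parsimony, assigning each shared peptide to exactly one protein;
5. sum S/N per protein and channel and rescale each protein's vector to
   sum to 100, giving the RA measurement used by all downstream statistics.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import defaultdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import channel_columns
from .simulate import DECOY_PREFIX

logger = logging.getLogger(__name__)

#: Exact minimum set cover is used for ambiguity groups up to this many
#: candidate proteins; larger groups fall back to the greedy cover, which is
#: within a ln(n_peptides)+1 factor of optimal.
EXACT_COVER_LIMIT = 12


class DegenerateInputError(ValueError):
    """Raised when an input is structurally unusable (e.g. an empty channel)."""


# ---------------------------------------------------------------------------
# PSM-level operations
# ---------------------------------------------------------------------------


def filter_low_sn(psms: pd.DataFrame, min_summed_sn: float = 100.0) -> pd.DataFrame:
    """Drop PSMs whose summed S/N over all channels is below the floor.

    The boundary is strict: a sum of exactly ``min_summed_sn`` is retained.
    """
    if psms.empty:
        return psms.copy()
    chans = channel_columns(psms)
    keep = psms[chans].sum(axis=1) >= min_summed_sn
    return psms.loc[keep].reset_index(drop=True)


def column_normalize(psms: pd.DataFrame) -> pd.DataFrame:
    """Equal-loading correction: rescale each channel to the mean channel total.

    Channel k is multiplied by ``mean(raw totals) / total_k``; afterwards all
    channel totals are equal to machine precision.
    """
    if psms.empty:
        raise DegenerateInputError("cannot normalize an empty PSM table")
    out = psms.copy()
    chans = channel_columns(out)
    totals = out[chans].sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise DegenerateInputError(
            f"channel(s) with non-positive total S/N: {', '.join(zero.index)}"
        )
    factors = totals.mean() / totals
    out[chans] = out[chans] * factors
    return out


# ---------------------------------------------------------------------------
# Protein-level scoring and FDR
# ---------------------------------------------------------------------------


def protein_probability(psms_of_protein: pd.DataFrame | Iterable[float]) -> float:
    """Protein-level probability: product of per-peptide posteriors.

    For multiple PSMs of the same peptide sequence the best posterior is
    used; the product is computed in log space.  A zero posterior yields
    probability 0 (flagged via a warning).
    """
    if isinstance(psms_of_protein, pd.DataFrame):
        best = psms_of_protein.groupby("peptide")["posterior"].max()
        posteriors = best.to_numpy(dtype=float)
    else:
        posteriors = np.asarray(list(psms_of_protein), dtype=float)
    if posteriors.size == 0:
        raise ValueError("protein_probability needs at least one peptide")
    if np.any((posteriors < 0) | (posteriors > 1)):
        raise ValueError("posteriors must lie in [0, 1]")
    if np.any(posteriors == 0):
        logger.warning("peptide with posterior 0 -> protein probability 0")
        return 0.0
    return float(math.exp(np.log(posteriors).sum()))


def base_protein_id(protein: str) -> str:
    """Strip the decoy prefix, giving the shared target/decoy pair identifier."""
    return protein[len(DECOY_PREFIX):] if protein.startswith(DECOY_PREFIX) else protein


def picked_protein_fdr(protein_scores: pd.DataFrame, fdr_target: float = 0.01) -> pd.DataFrame:
    """Picked target-decoy protein FDR.

    For every target/decoy pair (sharing a base identifier) only the
    higher-scoring member is kept; survivors are ranked by descending
    score; the FDR at a score cutoff is ``#decoys >= cutoff / #targets >=
    cutoff``; q-values are monotonized from the bottom of the ranking, and
    targets with ``q <= fdr_target`` are accepted.

    ``protein_scores`` needs columns ``protein`` and ``score``; decoys are
    recognised by the ``decoy_`` prefix.  Returns the picked table with
    ``q_value`` and ``accepted`` columns (decoys are never accepted).
    """
    if not 0.0 < fdr_target <= 1.0:
        raise ValueError(f"fdr_target must be in (0, 1], got {fdr_target}")
    df = protein_scores.copy()
    if df.empty:
        df["is_decoy"] = pd.Series(dtype=bool)
        df["q_value"] = pd.Series(dtype=float)
        df["accepted"] = pd.Series(dtype=bool)
        return df
    df["is_decoy"] = df["protein"].str.startswith(DECOY_PREFIX)
    df["base_protein"] = df["protein"].map(base_protein_id)

    # picking: keep the better-scoring member of each pair (target wins ties)
    df = df.sort_values(
        ["base_protein", "score", "is_decoy"], ascending=[True, False, True]
    ).drop_duplicates("base_protein", keep="first")

    df = df.sort_values(["score", "is_decoy", "protein"], ascending=[False, True, True])
    scores = df["score"].to_numpy()
    decoy = df["is_decoy"].to_numpy()
    # cumulative counts at-or-above each row's score; rows tied on score all
    # receive the counts at the end of their tie block
    n_dec = np.cumsum(decoy)
    n_tar = np.cumsum(~decoy)
    block_last = np.empty(len(scores), dtype=int)
    last = len(scores) - 1
    for i in range(len(scores) - 1, -1, -1):
        if i < len(scores) - 1 and scores[i] != scores[i + 1]:
            last = i
        block_last[i] = last
    n_dec_ge = n_dec[block_last]
    n_tar_ge = n_tar[block_last]
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_tar_ge > 0, n_dec_ge / np.maximum(n_tar_ge, 1), 1.0)
    fdr = np.minimum(fdr, 1.0)
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    df = df.assign(q_value=q)
    df["accepted"] = (~df["is_decoy"]) & (df["q_value"] <= fdr_target)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Parsimony protein inference
# ---------------------------------------------------------------------------


def _peptide_protein_map(psms: pd.DataFrame) -> dict[str, frozenset[str]]:
    pep_map: dict[str, set[str]] = defaultdict(set)
    for pep, prots in zip(psms["peptide"], psms["proteins"]):
        names = prots if isinstance(prots, (set, frozenset, list, tuple)) else str(prots).split(";")
        pep_map[pep].update(p for p in names if p)
    return {p: frozenset(s) for p, s in pep_map.items()}


def _exact_cover(peptides: list[frozenset[str]], proteins: list[str]) -> list[str]:
    """Smallest protein subset covering all peptides; ties broken by the
    lexicographically smallest sorted protein tuple."""
    for size in range(1, len(proteins) + 1):
        best: tuple[str, ...] | None = None
        for combo in itertools.combinations(sorted(proteins), size):
            cset = set(combo)
            if all(peps & cset for peps in peptides):
                if best is None or combo < best:
                    best = combo
        if best is not None:
            return list(best)
    return sorted(proteins)


def _greedy_cover(peptides: list[frozenset[str]], proteins: list[str]) -> list[str]:
    uncovered = set(range(len(peptides)))
    chosen: list[str] = []
    while uncovered:
        gain = {
            prot: sum(1 for i in uncovered if prot in peptides[i]) for prot in proteins
        }
        prot = min(gain, key=lambda p: (-gain[p], p))
        if gain[prot] == 0:
            break
        chosen.append(prot)
        uncovered -= {i for i in uncovered if prot in peptides[i]}
    return chosen


def parsimony_collapse(
    psms: pd.DataFrame,
) -> tuple[dict[str, str], set[str]]:
    """Maximum-parsimony protein inference.

    Returns a ``peptide -> protein`` assignment and the retained protein
    set: the minimum number of proteins explaining every observed peptide
    (exact minimum set cover per ambiguity group up to
    :data:`EXACT_COVER_LIMIT` candidate proteins, greedy beyond).  Each
    shared peptide is assigned to the retained candidate with the most
    distinct peptides, ties to the lexicographically smallest identifier.
    """
    pep_map = _peptide_protein_map(psms)
    if not pep_map:
        return {}, set()

    # connected components of the peptide-protein bipartite graph
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for pep, prots in pep_map.items():
        prots = sorted(prots)
        for p in prots:
            union("prot::" + prots[0], "prot::" + p)

    groups: dict[str, list[str]] = defaultdict(list)
    for pep, prots in pep_map.items():
        root = find("prot::" + sorted(prots)[0])
        groups[root].append(pep)

    retained: set[str] = set()
    assignment: dict[str, str] = {}
    for root in sorted(groups):
        peps = sorted(groups[root])
        pep_sets = [pep_map[p] for p in peps]
        prots = sorted(set().union(*pep_sets))
        cover = (
            _exact_cover(pep_sets, prots)
            if len(prots) <= EXACT_COVER_LIMIT
            else _greedy_cover(pep_sets, prots)
        )
        retained.update(cover)
        support = {
            prot: sum(1 for s in pep_sets if prot in s) for prot in cover
        }
        for pep, pset in zip(peps, pep_sets):
            candidates = [p for p in cover if p in pset]
            assignment[pep] = min(candidates, key=lambda p: (-support[p], p))
    return assignment, retained


# ---------------------------------------------------------------------------
# Rollup
# ---------------------------------------------------------------------------


def rollup_to_ra(
    psms: pd.DataFrame, assignment: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Sum S/N per protein and channel, then rescale each protein's vector
    to sum to 100 (the relative-abundance measurement).

    ``assignment`` maps each peptide to its single inferred protein; without
    it, every PSM must already name exactly one protein.  Output columns:
    ``protein``, ``n_peptides``, then ``ra_ch1..ra_chN``.  Proteins whose
    summed vector is all zero are dropped with a warning.
    """
    chans = channel_columns(psms)
    ra_cols = ["ra_" + c for c in chans]
    if psms.empty:
        return pd.DataFrame(columns=["protein", "n_peptides", *ra_cols])
    df = psms.copy()
    if assignment is not None:
        df["protein"] = df["peptide"].map(assignment)
        df = df.dropna(subset=["protein"])
    else:
        singles = df["proteins"].astype(str).str.split(";")
        if (singles.str.len() != 1).any():
            raise ValueError("rollup without an assignment requires single-protein PSMs")
        df["protein"] = singles.str[0]
    sums = df.groupby("protein")[chans].sum()
    n_pep = df.groupby("protein")["peptide"].nunique()
    totals = sums.sum(axis=1)
    dead = totals[totals <= 0].index
    if len(dead):
        logger.warning("dropping %d protein(s) with all-zero channel vectors", len(dead))
        sums = sums.drop(index=dead)
        totals = totals.drop(index=dead)
        n_pep = n_pep.drop(index=dead)
    ra = sums.div(totals, axis=0) * 100.0
    out = ra.reset_index()
    out.columns = ["protein", *ra_cols]
    out.insert(1, "n_peptides", n_pep.loc[out["protein"]].to_numpy())
    return out.sort_values("protein").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------


def quantify(
    psms: pd.DataFrame,
    fdr_target: float = 0.01,
    min_summed_sn: float = 100.0,
    order: tuple[str, str] = ("filter", "normalize"),
) -> pd.DataFrame:
    """Run the full PSM -> protein RA chain.

    The default order filters on raw summed S/N (an instrument-scale
    quantity) before the equal-loading normalization; ``order`` may be set
    to ``("normalize", "filter")`` to filter on normalized values instead.
    Returns the RA table with ``protein_probability`` and ``q_value``
    columns; only FDR-accepted target proteins appear.
    """
    if set(order) != {"filter", "normalize"}:
        raise ValueError("order must be a permutation of ('filter', 'normalize')")
    ra_cols_for_empty = ["protein", "n_peptides", "protein_probability", "q_value"]
    if psms.empty:
        return pd.DataFrame(columns=ra_cols_for_empty)
    df = psms
    for step in order:
        df = filter_low_sn(df, min_summed_sn) if step == "filter" else column_normalize(df)
    if df.empty:
        return pd.DataFrame(columns=ra_cols_for_empty)

    # protein scores over all candidate attributions (targets and decoys)
    pep_rows: list[tuple[str, str, float]] = []
    for pep, prots, post in zip(df["peptide"], df["proteins"], df["posterior"]):
        for prot in str(prots).split(";"):
            if prot:
                pep_rows.append((prot, pep, float(post)))
    attr = pd.DataFrame(pep_rows, columns=["protein", "peptide", "posterior"])
    best = attr.groupby(["protein", "peptide"])["posterior"].max().reset_index()
    with np.errstate(divide="ignore"):
        best["logp"] = np.log(best["posterior"].clip(lower=1e-300))
    scores = (
        best.groupby("protein")["logp"].sum().rename("score").reset_index()
    )

    picked = picked_protein_fdr(scores, fdr_target)
    accepted = set(picked.loc[picked["accepted"], "protein"])
    prob_map = dict(zip(scores["protein"], np.exp(scores["score"])))
    q_map = dict(zip(picked["protein"], picked["q_value"]))

    # keep target PSMs with >=1 accepted candidate, restricted to accepted candidates
    tgt = df.loc[~df["is_decoy"]].copy()
    kept_prots = tgt["proteins"].astype(str).map(
        lambda s: ";".join(sorted(p for p in s.split(";") if p in accepted))
    )
    tgt = tgt.assign(proteins=kept_prots)
    tgt = tgt.loc[tgt["proteins"] != ""].reset_index(drop=True)
    if tgt.empty:
        return pd.DataFrame(columns=ra_cols_for_empty)

    assignment, _retained = parsimony_collapse(tgt)
    ra = rollup_to_ra(tgt, assignment)
    ra.insert(2, "protein_probability", ra["protein"].map(prob_map))
    ra.insert(3, "q_value", ra["protein"].map(q_map))
    return ra
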