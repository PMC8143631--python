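"""Candidate nomination and end-to-end screen orchestration.

A protein is nominated as a putative APC/C substrate iff it passes the
differential screen (fold change above the calibrated threshold, more
than one peptide, p < 0.05) AND carries at least one passing degron hit
(D-box or KEN-box surviving the similarity/consensus/disorder/localization
filters).  Candidates are grouped by which degron classes passed —
D-box only, KEN-box only, or both — mirroring the screen's report layout.

:func:`run_screen` runs the whole chain in memory; :func:`run_pipeline`
is the file-based front end that reads the flat-file inputs, writes every
intermediate table, and records a machine-readable run manifest.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .differential import (
    Contrast,
    calibrate_fc_threshold,
    differential_analysis,
    screen_filter,
)
from .degron import scan_proteome
from .io import (
    read_disorder_tracks,
    read_fasta,
    read_known_substrates,
    read_localization,
    read_psm_table,
    write_json,
    write_ra_table,
)
from .quant import quantify

logger = logging.getLogger(__name__)

D_CLASSES = {"D_min", "D_ext"}
K_CLASSES = {"KEN"}

CANDIDATE_COLUMNS = [
    "protein", "degron_group", "fc", "p", "n_peptides",
    "best_d_similarity", "best_d_disorder",
    "best_k_similarity", "best_k_disorder",
    "previously_reported",
]

_GROUP_ORDER = {"D_box": 0, "KEN_box": 1, "D_and_KEN": 2}


def call_candidates(
    results: pd.DataFrame,
    screen_set: set[str],
    degron_hits: pd.DataFrame,
    all_hits: bool = False,
) -> pd.DataFrame:
    """Integrate the differential screen with passing degron hits.

    ``results`` is the differential table; ``screen_set`` the proteins that
    passed the screen cascade; ``degron_hits`` the scored hit table.  Only
    the best-scoring passing hit per class is reported per protein unless
    ``all_hits`` (then scores are slash-joined, e.g. ``0.94/0.90``).
    Within each degron group, records sort by descending fold change, ties
    broken lexicographically.
    """
    if degron_hits.empty:
        passing = degron_hits
    else:
        passing = degron_hits.loc[degron_hits["passes"].fillna(False).astype(bool)]
    rows = []
    stats = results.set_index("protein")
    for protein in sorted(screen_set):
        mine = passing.loc[passing["protein"] == protein] if not passing.empty else passing
        if mine.empty:
            continue
        d_hits = mine.loc[mine["degron_class"].isin(D_CLASSES)]
        k_hits = mine.loc[mine["degron_class"].isin(K_CLASSES)]
        if d_hits.empty and k_hits.empty:
            continue
        group = (
            "D_and_KEN" if (not d_hits.empty and not k_hits.empty)
            else "D_box" if not d_hits.empty
            else "KEN_box"
        )

        def best(hits: pd.DataFrame) -> tuple[object, object]:
            if hits.empty:
                return None, None
            hits = hits.sort_values("similarity", ascending=False)
            if all_hits:
                return (
                    "/".join(f"{s:.2f}" for s in hits["similarity"]),
                    "/".join(f"{d:.2f}" for d in hits["disorder"]),
                )
            top = hits.iloc[0]
            return float(top["similarity"]), float(top["disorder"])

        d_sim, d_dis = best(d_hits)
        k_sim, k_dis = best(k_hits)
        st = stats.loc[protein]
        rows.append(
            {
                "protein": protein,
                "degron_group": group,
                "fc": float(st["fc"]),
                "p": float(st["p"]),
                "n_peptides": int(st["n_peptides"]),
                "best_d_similarity": d_sim,
                "best_d_disorder": d_dis,
                "best_k_similarity": k_sim,
                "best_k_disorder": k_dis,
                "previously_reported": False,
            }
        )
    out = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    if not out.empty:
        out = out.sort_values(
            by=["degron_group", "fc", "protein"],
            key=lambda s: s.map(_GROUP_ORDER) if s.name == "degron_group" else (
                -s if s.name == "fc" else s
            ),
        ).reset_index(drop=True)
    return out


def annotate_known(candidates: pd.DataFrame, known_substrates: set[str]) -> pd.DataFrame:
    """Flag candidates previously reported as APC/C substrates."""
    out = candidates.copy()
    if not out.empty:
        out["previously_reported"] = out["protein"].isin(known_substrates)
    return out


# ---------------------------------------------------------------------------
# End-to-end screen
# ---------------------------------------------------------------------------


@dataclass
class ScreenOutput:
    ra: pd.DataFrame
    results: pd.DataFrame
    screen_set: set[str]
    degron_hits: pd.DataFrame
    candidates: pd.DataFrame
    manifest: dict


def run_screen(
    psms: pd.DataFrame,
    sequences: Mapping[str, str],
    disorder_tracks: Mapping[str, object] | None = None,
    localization: pd.DataFrame | None = None,
    known_substrates: set[str] | None = None,
    contrast: Contrast | None = None,
    fdr_target: float = 0.01,
    min_summed_sn: float = 100.0,
    fc_threshold: float | None = None,
    min_peptides: int = 2,
    alpha: float = 0.05,
    degron_classes: tuple[str, ...] = ("D_min", "D_ext", "KEN"),
    min_similarity: float = 0.75,
    min_disorder: float = 0.4,
    references: Mapping[str, list] | None = None,
    power_analysis: bool = True,
    all_hits: bool = False,
) -> ScreenOutput:
    """Quantify -> differential screen -> degron scan -> candidate call.

    If ``known_substrates`` is given, the fold-change threshold is
    calibrated as their median fold change in this run; otherwise
    ``fc_threshold`` (default 1.15) is used as-is.  The monotone cascade
    (candidates ⊆ screen-passing ⊆ quantified) is asserted on every run.
    """
    if contrast is None:
        raise ValueError("a treated-vs-control contrast is required")
    manifest: dict = {
        "version": __version__,
        "n_psms_in": int(len(psms)),
        "contrast": {"treated": contrast.treated, "control": contrast.control},
        "fdr_target": fdr_target,
        "min_summed_sn": min_summed_sn,
        "alpha": alpha,
        "min_peptides": min_peptides,
        "degron_filters": {
            "classes": list(degron_classes),
            "min_similarity": min_similarity,
            "min_disorder": min_disorder,
        },
    }
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if psms.empty:
        logger.warning("empty PSM input: producing an empty report")
        empty = pd.DataFrame(columns=CANDIDATE_COLUMNS)
        manifest.update(n_proteins_quantified=0, n_screen_passing=0, n_candidates=0,
                        fc_threshold_used=fc_threshold if fc_threshold else 1.15)
        return ScreenOutput(
            ra=pd.DataFrame(), results=pd.DataFrame(), screen_set=set(),
            degron_hits=pd.DataFrame(columns=["protein"]), candidates=empty,
            manifest=manifest,
        )
    ra = quantify(psms, fdr_target=fdr_target, min_summed_sn=min_summed_sn)
    timings["quantify"] = time.perf_counter() - t0
    logger.info("quantified %d proteins from %d PSMs", len(ra), len(psms))

    t0 = time.perf_counter()
    results = differential_analysis(ra, contrast, alpha=alpha, power_analysis=power_analysis)
    if known_substrates:
        try:
            threshold = calibrate_fc_threshold(results, known_substrates)
            manifest["fc_threshold_source"] = "calibrated_known_substrate_median"
        except ValueError:
            logger.warning(
                "no known substrates detected; falling back to fc_threshold=%s",
                fc_threshold if fc_threshold is not None else 1.15,
            )
            threshold = fc_threshold if fc_threshold is not None else 1.15
            manifest["fc_threshold_source"] = "fallback"
    else:
        threshold = fc_threshold if fc_threshold is not None else 1.15
        manifest["fc_threshold_source"] = "configured"
    screen_set = screen_filter(results, threshold, min_peptides=min_peptides, alpha=alpha)
    timings["differential"] = time.perf_counter() - t0
    logger.info("screen passed %d / %d proteins (fc >= %.4g)", len(screen_set), len(results), threshold)

    t0 = time.perf_counter()
    quantified = set(ra["protein"])
    scan_targets = {p: sequences[p] for p in sorted(screen_set) if p in sequences}
    missing = sorted(screen_set - set(sequences))
    if missing:
        logger.warning("%d screen-passing protein(s) lack sequences: %s",
                       len(missing), ", ".join(missing[:5]))
    degron_hits = scan_proteome(
        scan_targets, disorder_tracks, localization,
        classes=degron_classes, references=references,
        min_similarity=min_similarity, min_disorder=min_disorder,
    )
    timings["degron_scan"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    candidates = call_candidates(results, screen_set, degron_hits, all_hits=all_hits)
    candidates = annotate_known(candidates, known_substrates or set())
    timings["candidates"] = time.perf_counter() - t0

    nominated = set(candidates["protein"]) if not candidates.empty else set()
    assert nominated <= screen_set <= quantified, "filtering cascade must be monotone"

    manifest.update(
        n_proteins_quantified=len(quantified),
        n_screen_passing=len(screen_set),
        n_candidates=len(nominated),
        fc_threshold_used=float(threshold),
        timings_s={k: round(v, 4) for k, v in timings.items()},
    )
    return ScreenOutput(
        ra=ra, results=results, screen_set=screen_set,
        degron_hits=degron_hits, candidates=candidates, manifest=manifest,
    )


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path) -> ScreenOutput:
    """File-based screen run from a flat YAML-compatible config.

    Recognised keys: ``psms``, ``fasta``, ``disorder``, ``localization``,
    ``known_substrates`` (file paths); ``treated`` / ``control`` (channel
    lists); ``fdr_target``, ``min_summed_sn``, ``fc_threshold``,
    ``min_peptides``, ``alpha``, ``min_similarity``, ``min_disorder``,
    ``degron_classes``.  Writes the RA matrix, differential results, degron
    hits, candidate report (TSV + JSON) and the run manifest to ``out_dir``.
    """
    if not isinstance(config, Mapping):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    psms = read_psm_table(config["psms"])
    sequences = read_fasta(config["fasta"]) if config.get("fasta") else {}
    tracks = read_disorder_tracks(config["disorder"]) if config.get("disorder") else None
    localization = (
        read_localization(config["localization"]) if config.get("localization") else None
    )
    known = (
        read_known_substrates(config["known_substrates"])
        if config.get("known_substrates")
        else set()
    )
    contrast = Contrast(
        treated=list(config["treated"]), control=list(config["control"])
    )
    result = run_screen(
        psms,
        sequences,
        tracks,
        localization,
        known,
        contrast,
        fdr_target=float(config.get("fdr_target", 0.01)),
        min_summed_sn=float(config.get("min_summed_sn", 100.0)),
        fc_threshold=config.get("fc_threshold"),
        min_peptides=int(config.get("min_peptides", 2)),
        alpha=float(config.get("alpha", 0.05)),
        degron_classes=tuple(config.get("degron_classes", ("D_min", "D_ext", "KEN"))),
        min_similarity=float(config.get("min_similarity", 0.75)),
        min_disorder=float(config.get("min_disorder", 0.4)),
        all_hits=bool(config.get("all_hits", False)),
    )
    write_ra_table(result.ra, out / "protein_ra.tsv")
    result.results.to_csv(out / "differential.tsv", sep="\t", index=False)
    result.degron_hits.to_csv(out / "degron_hits.tsv", sep="\t", index=False)
    result.candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
    write_json(result.candidates.to_dict(orient="records"), out / "candidates.json")
    write_json(result.manifest, out / "manifest.json")
    return result
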