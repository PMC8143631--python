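"""Synthetic-data generators with known ground truth.

Three generators emulate the three data types the screen consumes:

* :func:`simulate_tmt` — a 10-plex TMT experiment (3 biological replicates
  per arm: a t0 baseline, a vehicle control, and a drug-treated arm, plus a
  bridge channel), producing a PSM-level table with target and decoy
  identifications, peptide posterior probabilities, and per-channel
  reporter signal-to-noise.
* :func:`simulate_proteome` — protein sequences with degron motifs planted
  in disordered regions, plus per-residue disorder tracks and a
  localization table.
* :func:`simulate_nuclei` — per-nucleus maximum-intensity tables for the
  high-content mitotic-fraction assay, and optionally synthetic nuclear
  images.

Every generator is a pure function of its configuration: the seed fixes
all randomness, so identical calls give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import AMINO_ACIDS, MOTIF_TEMPLATES

DECOY_PREFIX = "decoy_"


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV.

    Reporter S/N is positive and right-skewed, so noise is modelled as
    ``exp(N(-s^2/2, s))`` with ``s^2 = ln(1 + cv^2)``; cv=0 returns exact 1s.
    """
    if cv == 0:
        return np.ones(size)
    s = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * s * s, s, size=size))


# ---------------------------------------------------------------------------
# TMT experiment
# ---------------------------------------------------------------------------


@dataclass
class TmtSimConfig:
    """Parameters of the synthetic 10-plex TMT screen.

    Defaults mirror the study design: three biological replicates per arm,
    treatment-induced fold changes in [1.15, 3.6] for a minority of
    proteins, multiplicative reporter noise with a ~10% CV, a t0 arm that
    is quantified but excluded from the treated-vs-control contrast, and a
    bridge channel excluded from statistics.
    """

    n_proteins: int
    n_replicates_per_arm: int = 3
    frac_regulated: float = 0.05
    fold_change_range: tuple[float, float] = (1.15, 3.6)
    cv: float = 0.1
    peptides_per_protein: float = 4.0  # mean of 1 + Poisson(mean - 1)
    decoy_fraction: float = 0.1
    posterior_distributions: dict = field(
        default_factory=lambda: {"target": (40.0, 1.0), "decoy": (2.0, 8.0)}
    )
    base_intensity: float = 100.0
    abundance_sigma: float = 1.0  # lognormal spread of protein abundances
    shared_peptide_fraction: float = 0.05
    # previously reported substrates form their own regulated group whose
    # fold changes are lognormal around the study's median of 1.15
    known_substrate_fraction: float = 0.005
    known_substrate_fc_median: float = 1.15
    known_substrate_fc_sigma: float = 0.3
    include_t0: bool = True
    include_bridge: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be >= 0")
        if self.n_replicates_per_arm < 2:
            raise ValueError("need >= 2 replicates per arm")
        for name in ("frac_regulated", "decoy_fraction", "shared_peptide_fraction",
                     "known_substrate_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.fold_change_range
        if not (np.isfinite(lo) and np.isfinite(hi)) or lo <= 0 or hi < lo:
            raise ValueError("fold_change_range must be a positive interval")
        if not np.isfinite(self.base_intensity) or self.base_intensity <= 0:
            raise ValueError("base_intensity must be positive and finite")
        if self.cv < 0 or not np.isfinite(self.cv):
            raise ValueError("cv must be a non-negative finite fraction")
        if self.peptides_per_protein < 1:
            raise ValueError("peptides_per_protein mean must be >= 1")

    @property
    def design(self) -> dict[str, list[str]]:
        """Arm -> reporter channel columns, in plex order (t0 | control | treated | bridge)."""
        n = self.n_replicates_per_arm
        ch = 1
        design: dict[str, list[str]] = {}
        if self.include_t0:
            design["t0"] = [f"ch{ch + i}" for i in range(n)]
            ch += n
        design["control"] = [f"ch{ch + i}" for i in range(n)]
        ch += n
        design["treated"] = [f"ch{ch + i}" for i in range(n)]
        ch += n
        if self.include_bridge:
            design["bridge"] = [f"ch{ch}"]
        return design


@dataclass
class TmtGroundTruth:
    """Per-protein truth for a simulated TMT screen."""

    proteins: pd.DataFrame  # protein, abundance, true_fc, regulated, known_substrate
    design: dict[str, list[str]]
    config: TmtSimConfig
    #: common dilution applied to unregulated proteins in the treated arm so
    #: that channel totals stay equal (the equal-loading constraint); 1.0 in
    #: a null simulation
    loading_dilution: float = 1.0

    @property
    def known_substrates(self) -> set[str]:
        df = self.proteins
        return set(df.loc[df["known_substrate"], "protein"])

    @property
    def regulated(self) -> set[str]:
        df = self.proteins
        return set(df.loc[df["regulated"], "protein"])

    def to_dict(self) -> dict:
        return {
            "proteins": self.proteins.to_dict(orient="records"),
            "design": self.design,
            "config": asdict(self.config),
        }


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def simulate_tmt(config: TmtSimConfig) -> tuple[pd.DataFrame, TmtGroundTruth]:
    """Simulate a PSM-level table for a multiplexed TMT screen.

    Each PSM's per-channel S/N is ``base_intensity x protein abundance x
    peptide share x arm fold-change x lognormal noise``.  Regulated
    proteins carry a log-uniform fold change from ``fold_change_range`` in
    the treated arm only; known substrates carry lognormal fold changes
    around ``known_substrate_fc_median``; t0 and control arms sit at the
    baseline; the bridge channel is the all-sample average.  Because equal
    peptide mass is loaded per channel, fold changes act on the relative
    scale: unregulated proteins are diluted by a common factor (recorded
    as ``truth.loading_dilution``) so that expected channel totals are
    equal.  At cv=0 the treated/control mean ratio of any regulated
    protein equals its true fold change exactly, both in the raw table and
    after the quantification chain.  Decoy PSMs point at
    ``decoy_<protein>`` identifiers and draw low posteriors.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    design = config.design
    channels = [c for cols in design.values() for c in cols]
    psm_cols = ["psm_id", "peptide", "proteins", "is_decoy", "posterior", *channels]

    width = max(4, len(str(max(n, 1))))
    protein_ids = [f"P{i:0{width}d}" for i in range(1, n + 1)]

    abundance = np.exp(rng.normal(0.0, config.abundance_sigma, size=n))
    n_novel = int(round(config.frac_regulated * n))
    n_known = int(round(config.known_substrate_fraction * n))
    n_known = min(n_known, n - n_novel)
    picked = (
        rng.choice(n, size=n_novel + n_known, replace=False)
        if n_novel + n_known
        else np.array([], int)
    )
    novel_idx, known_idx = picked[:n_novel], picked[n_novel:]
    true_fc = np.ones(n)
    lo, hi = config.fold_change_range
    true_fc[novel_idx] = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_novel))
    true_fc[known_idx] = np.exp(
        rng.normal(
            math.log(config.known_substrate_fc_median),
            config.known_substrate_fc_sigma,
            size=n_known,
        )
    )
    known = np.zeros(n, dtype=bool)
    known[known_idx] = True

    truth_df = pd.DataFrame(
        {
            "protein": protein_ids,
            "abundance": abundance,
            "true_fc": true_fc,
            "regulated": np.isin(np.arange(n), picked),
            "known_substrate": known,
        }
    )
    truth = TmtGroundTruth(proteins=truth_df, design=design, config=config)

    if n == 0:
        return pd.DataFrame(columns=psm_cols), truth

    # target PSM metadata
    n_pep = 1 + rng.poisson(config.peptides_per_protein - 1.0, size=n)
    t_a, t_b = config.posterior_distributions["target"]
    seen_peptides: set[str] = set()
    peptides: list[str] = []
    protein_lists: list[str] = []
    posteriors: list[float] = []
    prot_idx: list[int] = []
    baseline: list[float] = []
    for i, prot in enumerate(protein_ids):
        for _ in range(n_pep[i]):
            pep = _random_peptide(rng, int(rng.integers(8, 21)))
            while pep in seen_peptides:
                pep = _random_peptide(rng, int(rng.integers(8, 21)))
            seen_peptides.add(pep)
            prots = [prot]
            if n > 1 and rng.random() < config.shared_peptide_fraction:
                other = int(rng.integers(n - 1))
                other = other + 1 if other >= i else other
                prots.append(protein_ids[other])
            pep_share = float(np.exp(rng.normal(0.0, 0.5)))
            peptides.append(pep)
            protein_lists.append(";".join(sorted(set(prots))))
            posteriors.append(float(np.clip(rng.beta(t_a, t_b), 1e-12, 1.0)))
            prot_idx.append(i)
            baseline.append(config.base_intensity * abundance[i] * pep_share)

    # Channel means on the relative-abundance scale.  Equal peptide mass is
    # loaded per channel, so planted fold changes act on a protein's share
    # of the channel: regulated rows gain their fold change in the treated
    # arm and everything else is diluted by a common factor so that every
    # channel's total matches the baseline (equal loading by construction).
    s = np.asarray(baseline)
    fc_row = true_fc[np.asarray(prot_idx, dtype=int)] if len(s) else np.empty(0)
    reg_row = fc_row != 1.0
    sample_cols = [c for arm, cols in design.items() if arm != "bridge" for c in cols]
    mu = pd.DataFrame(
        np.tile(s[:, None], (1, len(channels))), columns=channels
    )
    treated_cols = design["treated"]
    mu[treated_cols] = np.tile(
        (s * np.where(reg_row, fc_row, 1.0))[:, None], (1, len(treated_cols))
    )
    t0_total = s.sum()
    unreg_mass = s[~reg_row].sum()
    if unreg_mass > 0:
        gamma = (t0_total - (s * fc_row)[reg_row].sum()) / unreg_mass
        gamma = max(gamma, 1e-9)
        mu.loc[~reg_row, treated_cols] *= gamma
        truth.loading_dilution = float(gamma)
    if config.include_bridge:
        mu[design["bridge"][0]] = mu[sample_cols].mean(axis=1)

    noise = _lognormal_noise(rng, config.cv, mu.shape)
    values = mu.to_numpy() * noise
    rows: list[dict] = []
    for j in range(len(s)):
        row = {
            "peptide": peptides[j],
            "proteins": protein_lists[j],
            "is_decoy": False,
            "posterior": posteriors[j],
        }
        row.update({c: values[j, k] for k, c in enumerate(channels)})
        rows.append(row)

    # decoy PSMs: incorrect matches paired to target proteins via the decoy_ prefix
    n_target_psms = len(rows)
    n_decoy = int(round(config.decoy_fraction / (1.0 - config.decoy_fraction) * n_target_psms)) \
        if config.decoy_fraction < 1.0 else 0
    d_a, d_b = config.posterior_distributions["decoy"]
    for _ in range(n_decoy):
        i = int(rng.integers(n))
        pep = _random_peptide(rng, int(rng.integers(8, 21)))
        while pep in seen_peptides:
            pep = _random_peptide(rng, int(rng.integers(8, 21)))
        seen_peptides.add(pep)
        base = config.base_intensity * float(np.exp(rng.normal(-0.5, config.abundance_sigma)))
        row = {
            "peptide": pep,
            "proteins": DECOY_PREFIX + protein_ids[i],
            "is_decoy": True,
            "posterior": float(np.clip(rng.beta(d_a, d_b), 1e-12, 1.0)),
        }
        noise = _lognormal_noise(rng, config.cv, len(channels))
        for c, nz in zip(channels, noise):
            row[c] = base * nz
        rows.append(row)

    psms = pd.DataFrame(rows)
    psms.insert(0, "psm_id", [f"psm{j + 1:06d}" for j in range(len(psms))])
    return psms[psm_cols], truth


# ---------------------------------------------------------------------------
# Proteome with planted degrons
# ---------------------------------------------------------------------------


@dataclass
class ProteomeGroundTruth:
    """Planted-degron bookkeeping: one row per planted motif instance."""

    planted: pd.DataFrame  # protein, degron_class, start, end, motif_seq (1-based inclusive)
    lengths: dict[str, int]

    def spans_for(self, protein: str) -> list[tuple[int, int, str]]:
        df = self.planted
        sel = df[df["protein"] == protein]
        return list(zip(sel["start"], sel["end"], sel["degron_class"]))


def motif_instance(
    degron_class: str,
    rng: np.random.Generator,
    alphabet: str = AMINO_ACIDS,
    sequence: str | None = None,
) -> str:
    """A concrete motif: anchored residues fixed, wildcards random (or from
    ``sequence`` if given)."""
    length, anchors = MOTIF_TEMPLATES[degron_class]
    if sequence is not None:
        if len(sequence) != length:
            raise ValueError(f"{degron_class} instance must have length {length}")
        for pos, res in anchors.items():
            if sequence[pos] != res:
                raise ValueError(f"anchored residue {res} missing at offset {pos}")
        return sequence
    wild = [c for c in alphabet if True]
    return "".join(
        anchors.get(i, wild[int(rng.integers(len(wild)))]) for i in range(length)
    )


def simulate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (150, 500),
    planted_degrons: Sequence[tuple[str, int]] = (),
    seed: int = 0,
    alphabet: str = AMINO_ACIDS,
    planted_sequences: Mapping[str, Sequence[str]] | None = None,
    background_disorder: tuple[float, float] = (0.0, 0.39),
    planted_disorder: tuple[float, float] = (0.55, 0.95),
    frac_secreted: float = 0.0,
) -> tuple[dict[str, str], dict[str, np.ndarray], pd.DataFrame, ProteomeGroundTruth]:
    """Random protein sequences with degron motifs planted in disordered regions.

    ``planted_degrons`` is a list of ``(class, count)`` pairs; each instance
    is placed at a random, non-overlapping position in a random protein.
    Background residues are uniform over ``alphabet``; the disorder track is
    uniform below 0.4 outside planted spans and above 0.55 inside them, so
    planted degrons always clear the disorder filter.
    ``planted_sequences`` optionally supplies explicit motif instances per
    class (cycled through), e.g. reference degrons that score similarity 1.
    """
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    if lo < 1:
        raise ValueError("lengths must be >= 1")
    max_motif = max(
        (MOTIF_TEMPLATES[c][0] for c, k in planted_degrons if k > 0), default=0
    )
    if max_motif > lo:
        raise ValueError(
            f"length_range lower bound {lo} is shorter than the longest planted motif ({max_motif})"
        )

    width = max(4, len(str(max(n_proteins, 1))))
    names = [f"S{i:0{width}d}" for i in range(1, n_proteins + 1)]
    letters = list(alphabet)
    seqs = {
        name: "".join(rng.choice(letters, size=int(rng.integers(lo, hi + 1))))
        for name in names
    }
    tracks = {
        name: rng.uniform(*background_disorder, size=len(seq))
        for name, seq in seqs.items()
    }

    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in names}
    planted_rows: list[dict] = []
    for degron_class, count in planted_degrons:
        length, _ = MOTIF_TEMPLATES[degron_class]
        supplied = list(planted_sequences.get(degron_class, [])) if planted_sequences else []
        for k in range(count):
            inst = (
                motif_instance(degron_class, rng, alphabet, supplied[k % len(supplied)])
                if supplied
                else motif_instance(degron_class, rng, alphabet)
            )
            placed = False
            for _ in range(200):
                name = names[int(rng.integers(n_proteins))]
                seq = seqs[name]
                if len(seq) < length:
                    continue
                start0 = int(rng.integers(len(seq) - length + 1))
                span = (start0, start0 + length - 1)
                if any(a <= span[1] and span[0] <= b for a, b in occupied[name]):
                    continue
                seqs[name] = seq[:start0] + inst + seq[start0 + length:]
                tracks[name][start0: start0 + length] = rng.uniform(
                    *planted_disorder, size=length
                )
                occupied[name].append(span)
                planted_rows.append(
                    {
                        "protein": name,
                        "degron_class": degron_class,
                        "start": start0 + 1,
                        "end": start0 + length,
                        "motif_seq": inst,
                    }
                )
                placed = True
                break
            if not placed:
                raise RuntimeError("could not place planted motif without overlap")

    secreted = rng.random(n_proteins) < frac_secreted
    localization = pd.DataFrame(
        {
            "protein": names,
            "intracellular": ~secreted,
            "secreted": secreted,
        }
    )
    truth = ProteomeGroundTruth(
        planted=pd.DataFrame(
            planted_rows, columns=["protein", "degron_class", "start", "end", "motif_seq"]
        ),
        lengths={name: len(seq) for name, seq in seqs.items()},
    )
    return seqs, tracks, localization, truth


# ---------------------------------------------------------------------------
# Combined screen dataset (TMT + proteome + annotations)
# ---------------------------------------------------------------------------


@dataclass
class ScreenDataset:
    """A complete synthetic screen: PSMs, proteome, annotations, and truth."""

    psms: pd.DataFrame
    tmt_truth: TmtGroundTruth
    sequences: dict[str, str]
    disorder_tracks: dict[str, np.ndarray]
    localization: pd.DataFrame
    planted_degrons: pd.DataFrame  # protein, degron_class, start, end, motif_seq
    known_substrates: set[str]

    @property
    def substrates(self) -> set[str]:
        """Novel planted substrates: degron-bearing regulated proteins drawn
        from ``substrate_fc_range`` (the recovery targets).  Known
        substrates are excluded — their fold changes centre on 1.15 and the
        screen is not expected to recover them all."""
        with_degron = set(self.planted_degrons["protein"])
        return (self.tmt_truth.regulated - self.known_substrates) & with_degron


def simulate_screen_dataset(
    n_proteins: int = 400,
    n_substrates: int = 20,
    substrate_fc_range: tuple[float, float] = (1.5, 3.0),
    n_known: int = 25,
    cv: float = 0.05,
    seed: int = 0,
    length_range: tuple[int, int] = (120, 400),
    degron_background_fraction: float = 0.1,
    **tmt_kwargs,
) -> ScreenDataset:
    """Generate every input of the end-to-end screen with known ground truth.

    ``n_substrates`` novel regulated proteins receive a treatment fold
    change from ``substrate_fc_range`` and a planted, filter-passing degron
    (reference D-box and KEN-box instances alternate, placed in a
    high-disorder region).  ``n_known`` previously reported substrates get
    lognormal fold changes around the study median of 1.15 and planted
    degrons as well; their identifiers form the known-substrate list used
    to calibrate the fold-change threshold.  A background fraction of
    unregulated proteins also carries degrons, so nomination specificity is
    exercised.
    """
    from .degron import load_reference_degrons

    config = TmtSimConfig(
        n_proteins=n_proteins,
        frac_regulated=n_substrates / n_proteins if n_proteins else 0.0,
        known_substrate_fraction=n_known / n_proteins if n_proteins else 0.0,
        fold_change_range=substrate_fc_range,
        cv=cv,
        seed=seed,
        **tmt_kwargs,
    )
    psms, truth = simulate_tmt(config)
    rng = np.random.default_rng(seed + 1)
    refs = load_reference_degrons()

    names = list(truth.proteins["protein"])
    letters = list(AMINO_ACIDS)
    lo, hi = length_range
    sequences: dict[str, str] = {}
    tracks: dict[str, np.ndarray] = {}
    planted_rows: list[dict] = []

    regulated = truth.regulated
    background_with_degron = {
        name
        for name in names
        if name not in regulated and rng.random() < degron_background_fraction
    }
    classes_cycle = ["D_ext", "KEN"]
    k = 0
    for name in names:
        seq = "".join(rng.choice(letters, size=int(rng.integers(lo, hi + 1))))
        track = rng.uniform(0.0, 0.39, size=len(seq))
        if name in regulated or name in background_with_degron:
            cls = classes_cycle[k % 2]
            k += 1
            inst = refs[cls][k % len(refs[cls])]
            length = len(inst)
            start0 = int(rng.integers(len(seq) - length + 1))
            seq = seq[:start0] + inst + seq[start0 + length:]
            track[start0: start0 + length] = rng.uniform(0.55, 0.95, size=length)
            planted_rows.append(
                {
                    "protein": name,
                    "degron_class": cls,
                    "start": start0 + 1,
                    "end": start0 + length,
                    "motif_seq": inst,
                }
            )
        sequences[name] = seq
        tracks[name] = track

    localization = pd.DataFrame(
        {"protein": names, "intracellular": True, "secreted": False}
    )
    return ScreenDataset(
        psms=psms,
        tmt_truth=truth,
        sequences=sequences,
        disorder_tracks=tracks,
        localization=localization,
        planted_degrons=pd.DataFrame(
            planted_rows, columns=["protein", "degron_class", "start", "end", "motif_seq"]
        ),
        known_substrates=truth.known_substrates,
    )


# ---------------------------------------------------------------------------
# Nuclei for the mitotic-fraction assay
# ---------------------------------------------------------------------------


@dataclass
class NucleiSimParams:
    """Lognormal intensity parameters for interphase vs mitotic nuclei.

    Mitotic chromatin is condensed, so its DNA-stain maximum intensity is
    several-fold brighter; the location parameters must keep the two
    populations separable.
    """

    interphase_median: float = 2000.0
    interphase_sigma: float = 0.25
    mitotic_median: float = 9000.0
    mitotic_sigma: float = 0.2

    def __post_init__(self) -> None:
        if self.mitotic_median <= self.interphase_median:
            raise ValueError("mitotic intensity location must exceed interphase")


def simulate_nuclei(
    n_cells_per_condition: int,
    mitotic_fraction_per_condition: Mapping[str, float],
    intensity_params: NucleiSimParams | None = None,
    seed: int = 0,
    n_wells: int = 3,
) -> pd.DataFrame:
    """Per-nucleus maximum-intensity table with ground-truth mitotic flags.

    Per condition, exactly ``round(fraction x n)`` cells draw from the
    mitotic lognormal and the rest from the interphase lognormal; cells are
    split round-robin across wells (wells are pooled downstream).
    """
    p = intensity_params or NucleiSimParams()
    rng = np.random.default_rng(seed)
    rows = []
    for condition, frac in mitotic_fraction_per_condition.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"mitotic fraction for {condition!r} outside [0, 1]")
        n_mit = int(round(frac * n_cells_per_condition))
        flags = np.zeros(n_cells_per_condition, dtype=bool)
        flags[:n_mit] = True
        rng.shuffle(flags)
        inten = np.where(
            flags,
            rng.lognormal(math.log(p.mitotic_median), p.mitotic_sigma, n_cells_per_condition),
            rng.lognormal(math.log(p.interphase_median), p.interphase_sigma, n_cells_per_condition),
        )
        for i in range(n_cells_per_condition):
            rows.append(
                {
                    "condition": condition,
                    "well": f"{condition}_w{(i % n_wells) + 1}",
                    "max_intensity": inten[i],
                    "is_mitotic": bool(flags[i]),
                }
            )
    return pd.DataFrame(rows, columns=["condition", "well", "max_intensity", "is_mitotic"])


def simulate_nucleus_image(
    n_nuclei: int,
    shape: tuple[int, int] = (256, 256),
    peak_intensities: Sequence[float] | None = None,
    nucleus_sigma: float = 3.0,
    background: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    min_separation: int = 24,
) -> tuple[np.ndarray, pd.DataFrame]:
    """A synthetic 16-bit nuclear image: non-touching Gaussian nuclei on a
    flat background.  Returns the image and the planted truth (centres and
    peak values = background + amplitude at the centre pixel)."""
    rng = np.random.default_rng(seed)
    img = np.full(shape, background, dtype=float)
    peaks = list(peak_intensities) if peak_intensities is not None else [
        3000.0 + 500.0 * i for i in range(n_nuclei)
    ]
    if len(peaks) != n_nuclei:
        raise ValueError("need one peak intensity per nucleus")
    centres: list[tuple[int, int]] = []
    margin = min_separation
    for _ in range(10000):
        if len(centres) == n_nuclei:
            break
        r = int(rng.integers(margin, shape[0] - margin))
        c = int(rng.integers(margin, shape[1] - margin))
        if all(abs(r - r0) + abs(c - c0) >= min_separation for r0, c0 in centres):
            centres.append((r, c))
    if len(centres) < n_nuclei:
        raise RuntimeError("could not place non-touching nuclei; enlarge the image")
    yy, xx = np.mgrid[0: shape[0], 0: shape[1]]
    for (r, c), amp in zip(centres, peaks):
        img += amp * np.exp(-(((yy - r) ** 2 + (xx - c) ** 2) / (2 * nucleus_sigma**2)))
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=shape)
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    truth = pd.DataFrame(
        {
            "row": [r for r, _ in centres],
            "col": [c for _, c in centres],
            "peak": [min(65535, round(background + a)) for a in peaks],
        }
    )
    return img, truth
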