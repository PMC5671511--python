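"""Seeded generators for synthetic inputs with known ground truth.

Three generators cover the package's input surface:

* :func:`simulate_cds_set` — coding sequences whose codons are drawn from
  within-family multinomials, with a planted preferred-codon boost in a
  biased gene subset (the "highly expressed" contrast).
* :func:`simulate_expression` — log-scale intensities whose location is
  raised for the biased subset, so expression rank tracks planted bias.
* :func:`simulate_plate` — two-channel plates where one multiplicative
  efficiency factor per well scales both channels, with channel-specific
  multiplicative log-normal noise and additive blank offsets.

Every generator is a pure function of (config, seed) and returns a truth
table alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bias_detection import ExpressionTable
from .codon_core import CodingSequence, FrequencyTable, GeneticCode, standard_code
from .fluor_norm import Plate

__all__ = [
    "CdsSimConfig",
    "CdsTruth",
    "simulate_cds_set",
    "simulate_expression",
    "PlateSimConfig",
    "simulate_plate",
]

DEFAULT_BIASED_FAMILIES = ("E", "F", "K", "N", "Q")


@dataclass(frozen=True)
class CdsSimConfig:
    """Configuration of the synthetic CDS generator.

    ``length_range`` is the inclusive codon-count interval of a gene
    including the forced ATG start, excluding the appended stop.
    ``bias_strength`` multiplies the planted preferred codon's within-family
    probability (then renormalized) in biased genes; 1 is the null.
    """

    n_genes: int = 220
    length_range: tuple[int, int] = (100, 200)
    biased_subset_size: int = 20
    bias_strength: float = 5.0
    biased_families: tuple[str, ...] = DEFAULT_BIASED_FAMILIES
    base_usage: FrequencyTable | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (2 <= lo <= hi):
            raise ValueError("length_range must satisfy 2 <= lo <= hi")
        if not 0 <= self.biased_subset_size <= self.n_genes:
            raise ValueError("biased_subset_size must lie in [0, n_genes]")
        if self.bias_strength < 1:
            raise ValueError("bias_strength must be >= 1")
        if self.base_usage is not None and self.base_usage.scope != "within_family":
            raise ValueError("base_usage must be a within_family frequency table")


@dataclass(frozen=True)
class CdsTruth:
    """Ground truth of one simulated CDS set."""

    genes: pd.DataFrame  # gene_id, group, n_codons
    planted_targets: dict[str, str]  # biased family -> preferred codon
    biased_families: tuple[str, ...]

    @property
    def biased_gene_ids(self) -> set[str]:
        return set(self.genes.loc[self.genes["group"] == "biased", "gene_id"])


def _family_probs(
    cfg: CdsSimConfig, code: GeneticCode
) -> dict[str, tuple[tuple[str, ...], np.ndarray]]:
    probs = {}
    for aa in code.amino_acids:
        fam = code.family(aa)
        if cfg.base_usage is None:
            p = np.full(len(fam), 1.0 / len(fam))
        else:
            raw = np.array([cfg.base_usage.freq.get(c, 0.0) for c in fam])
            if raw.sum() <= 0:
                raise ValueError(f"base_usage undefined for family {aa}")
            p = raw / raw.sum()
        probs[aa] = (fam, p)
    return probs


def simulate_cds_set(
    cfg: CdsSimConfig, code: GeneticCode | None = None
) -> tuple[list[CodingSequence], CdsTruth]:
    """Draw a seeded CDS set with a planted codon-preference shift.

    The first ``biased_subset_size`` genes form the biased group.  Each
    biased family's planted preferred codon is chosen at random (recorded in
    the truth table); in biased genes its probability is multiplied by
    ``bias_strength`` and the family renormalized.  Deterministic given the
    config (byte-identical FASTA for equal seeds).
    """
    code = code or standard_code()
    rng = np.random.default_rng(cfg.seed)
    probs = _family_probs(cfg, code)

    planted: dict[str, str] = {}
    for aa in sorted(cfg.biased_families):
        fam, p = probs[aa]
        if len(fam) < 2:
            raise ValueError(f"cannot plant bias in single-codon family {aa}")
        planted[aa] = str(rng.choice(fam, p=p))

    boosted: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
    for aa, (fam, p) in probs.items():
        if aa in planted:
            q = p.copy()
            q[fam.index(planted[aa])] *= cfg.bias_strength
            boosted[aa] = (fam, q / q.sum())
        else:
            boosted[aa] = (fam, p)

    lo, hi = cfg.length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_genes)
    stops = np.array(code.stop_codons)
    gene_stops = rng.choice(stops, size=cfg.n_genes)

    aa_pool = np.array(code.amino_acids)
    body_lengths = lengths - 1  # ATG start is forced
    total_body = int(body_lengths.sum())
    body_aas = rng.choice(aa_pool, size=total_body)

    offsets = np.concatenate([[0], np.cumsum(body_lengths)])
    gene_of_pos = np.repeat(np.arange(cfg.n_genes), body_lengths)
    biased_pos = gene_of_pos < cfg.biased_subset_size

    codons = np.empty(total_body, dtype=object)
    for aa in code.amino_acids:  # fixed draw order for determinism
        for is_biased, table in ((False, probs), (True, boosted)):
            idx = np.flatnonzero((body_aas == aa) & (biased_pos == is_biased))
            if idx.size == 0:
                continue
            fam, p = table[aa]
            codons[idx] = rng.choice(np.array(fam), size=idx.size, p=p)

    width = len(str(cfg.n_genes))
    records: list[CodingSequence] = []
    rows = []
    for i in range(cfg.n_genes):
        body = "".join(codons[offsets[i] : offsets[i + 1]])
        seq = "ATG" + body + str(gene_stops[i])
        gene_id = f"gene{i + 1:0{width}d}"
        records.append(CodingSequence(id=gene_id, seq=seq))
        rows.append(
            {
                "gene_id": gene_id,
                "group": "biased" if i < cfg.biased_subset_size else "background",
                "n_codons": int(lengths[i]) + 1,
            }
        )
    truth = CdsTruth(
        genes=pd.DataFrame(rows),
        planted_targets=planted,
        biased_families=tuple(sorted(cfg.biased_families)),
    )
    return records, truth


def simulate_expression(
    gene_ids: list[str],
    biased_subset: set[str],
    loc_background: float = 12.0,
    loc_biased: float = 13.2,
    sigma: float = 0.5,
    seed: int = 0,
) -> ExpressionTable:
    """Log-normal intensities with a higher location for the biased subset.

    Defaults put the background around e^12 ~ 1.6e5 and the biased genes
    around e^13.2 ~ 5.4e5, mimicking intensity strata at 2e5 / 4.5e5.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    locs = np.where(
        np.isin(np.array(gene_ids), sorted(biased_subset)), loc_biased, loc_background
    )
    values = rng.lognormal(mean=locs, sigma=sigma)
    return ExpressionTable.from_pairs(zip(gene_ids, values))


@dataclass(frozen=True)
class PlateSimConfig:
    """Configuration of the dual-channel plate generator.

    Per sample well: GFP = strength x base_signal x efficiency x noise +
    blank; mCherry = base_signal x efficiency x noise + blank, with
    ``efficiency`` a mean-1 log-normal of c.v. ``efficiency_cv`` drawn per
    well and ``noise`` mean-1 log-normals of c.v. ``channel_noise_cv`` drawn
    per channel.  Blank wells read exactly ``blank_level``; background wells
    (non-transfected) carry no reporter signal.
    """

    constructs: tuple[tuple[str, float], ...] = (("ref", 1.0), ("strong", 5.0))
    n_transfections: int = 4
    wells_per_transfection: int = 3
    efficiency_cv: float = 0.5
    channel_noise_cv: float = 0.05
    blank_level: float = 300.0
    base_signal: float = 1000.0
    n_blank_wells: int = 3
    n_background_wells: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.constructs:
            raise ValueError("need at least one construct")
        if any(s <= 0 for _, s in self.constructs):
            raise ValueError("construct strengths must be positive")
        if self.efficiency_cv < 0 or self.channel_noise_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")


def _mean_one_lognormal(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def simulate_plate(cfg: PlateSimConfig) -> tuple[Plate, pd.DataFrame]:
    """Emit a plate plus a truth table of strengths and efficiencies."""
    rng = np.random.default_rng(cfg.seed)
    rows = []
    truth_rows = []
    for construct, strength in cfg.constructs:
        for t in range(1, cfg.n_transfections + 1):
            transfection = f"{construct}_t{t}"
            effs = _mean_one_lognormal(rng, cfg.efficiency_cv, cfg.wells_per_transfection)
            noise_g = _mean_one_lognormal(rng, cfg.channel_noise_cv, cfg.wells_per_transfection)
            noise_m = _mean_one_lognormal(rng, cfg.channel_noise_cv, cfg.wells_per_transfection)
            for w in range(cfg.wells_per_transfection):
                well = f"{transfection}_w{w + 1}"
                gfp = strength * cfg.base_signal * effs[w] * noise_g[w] + cfg.blank_level
                mch = cfg.base_signal * effs[w] * noise_m[w] + cfg.blank_level
                rows.append((well, construct, "sample", "GFP", gfp, transfection))
                rows.append((well, construct, "sample", "mCherry", mch, transfection))
                truth_rows.append(
                    {
                        "well": well,
                        "construct": construct,
                        "transfection": transfection,
                        "strength": strength,
                        "efficiency": effs[w],
                    }
                )
    for i in range(1, cfg.n_blank_wells + 1):
        for channel in ("GFP", "mCherry"):
            rows.append((f"blank_w{i}", "blank", "blank", channel, cfg.blank_level, f"blank_w{i}"))
    for i in range(1, cfg.n_background_wells + 1):
        for channel in ("GFP", "mCherry"):
            rows.append(
                (f"bg_w{i}", "background", "background", channel, cfg.blank_level, f"bg_w{i}")
            )
    data = pd.DataFrame(
        rows, columns=["well", "construct", "role", "channel", "value", "transfection"]
    )
    return Plate(data=data), pd.DataFrame(truth_rows)
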