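"""Synthetic inputs with planted ground truth for every analysis stage.

The generators emulate the statistical structure the downstream statistics
assume, not any particular assay:

* paired-species DE summary tables: per-feature effects on the z scale,
  z = s*effect_mu + eps with eps ~ Normal(0, 1), two-sided normal p-values,
  L2FC = z * lfc_scale, per-table BH adjustment.  Concordant homolog pairs
  share the direction s across species, discordant pairs flip it, the rest
  are pure noise.  A fraction of human features receives a second zebrafish
  paralog (same direction, independent noise) mirroring the
  dre-miR-21-1/-2 pairing.
* four-contrast factorial tables whose planted classes match the set-logic
  definitions in :mod:`mirconcord.factorial_class`;
* gene-set collections that share a planted core over a common background;
* 3'UTR sequences with planted exact seed-match (8mer) sites on a uniform
  background;
* 2-D point patterns inside a polygonal ROI: homogeneous Poisson, or simple
  sequential inhibition when a minimum spacing is requested.

Every generator is driven by a single integer seed and is fully
deterministic: one config, one output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Point, Polygon

from .de_io import DETable, bh_adjust
from .cross_species import HomologyMap
from .enrichment import reverse_complement
from .factorial_class import ContrastQuad
from .de_io import call_significant

# ---------------------------------------------------------------------------
# paired-species DE tables


@dataclass
class SimDEPairConfig:
    """Generative settings for one paired-species DE experiment.

    effect_mu is the planted |mean| on the z scale for dysregulated
    features; lfc_scale maps z to log2 fold-change units.
    """

    n_homologs: int = 1000
    n_extra_per_species: int = 100
    prop_concordant: float = 0.1
    prop_discordant: float = 0.02
    effect_mu: float = 5.0
    lfc_scale: float = 1.0
    paralog_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prop_concordant", "prop_discordant", "paralog_rate"):
            v = getattr(self, name)
            if not np.isfinite(v) or not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.prop_concordant + self.prop_discordant > 1:
            raise ValueError("prop_concordant + prop_discordant must be <= 1")
        if not np.isfinite(self.effect_mu) or self.effect_mu < 0:
            raise ValueError("effect_mu must be finite and non-negative")
        if not np.isfinite(self.lfc_scale) or self.lfc_scale <= 0:
            raise ValueError("lfc_scale must be positive")
        if self.n_homologs <= 0 or self.n_extra_per_species < 0:
            raise ValueError("invalid feature counts")


def _z_to_table(contrast_id: str, ids: list[str], z: np.ndarray, lfc_scale: float) -> DETable:
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 1e-300, 1.0)
    df = pd.DataFrame(
        {
            "feature_id": ids,
            "log2FoldChange": z * lfc_scale,
            "pvalue": p,
            "padj": bh_adjust(p),
        }
    )
    return DETable(contrast_id, df)


def simulate_de_pair(
    config: SimDEPairConfig,
) -> tuple[DETable, DETable, HomologyMap, pd.DataFrame]:
    """Paired human/zebrafish DE tables + homology map + truth labels.

    Truth is one row per homolog pair (keyed by the human id) with label in
    {null, concordant_up, concordant_down, discordant}.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_homologs
    u = rng.random(n)
    is_conc = u < cfg.prop_concordant
    is_disc = (u >= cfg.prop_concordant) & (u < cfg.prop_concordant + cfg.prop_discordant)
    s = rng.choice([-1.0, 1.0], size=n)

    mu_h = np.where(is_conc | is_disc, s * cfg.effect_mu, 0.0)
    mu_f = np.where(is_conc, s, np.where(is_disc, -s, 0.0)) * cfg.effect_mu
    z_h = mu_h + rng.standard_normal(n)
    z_f = mu_f + rng.standard_normal(n)

    human_ids = [f"hsa-mir-{i:04d}" for i in range(n)]
    fish_ids = [f"dre-mir-{i:04d}-1" for i in range(n)]
    pairs = [(h, f) for h, f in zip(human_ids, fish_ids)]

    has_paralog = rng.random(n) < cfg.paralog_rate
    par_idx = np.nonzero(has_paralog)[0]
    z_par = mu_f[par_idx] + rng.standard_normal(len(par_idx))
    par_ids = [f"dre-mir-{i:04d}-2" for i in par_idx]
    pairs += [(human_ids[i], pid) for i, pid in zip(par_idx, par_ids)]

    ne = cfg.n_extra_per_species
    extra_h_ids = [f"hsa-mir-x{i:04d}" for i in range(ne)]
    extra_f_ids = [f"dre-mir-x{i:04d}" for i in range(ne)]
    z_extra_h = rng.standard_normal(ne)
    z_extra_f = rng.standard_normal(ne)

    human = _z_to_table(
        "human", human_ids + extra_h_ids, np.concatenate([z_h, z_extra_h]), cfg.lfc_scale
    )
    fish = _z_to_table(
        "fish",
        fish_ids + par_ids + extra_f_ids,
        np.concatenate([z_f, z_par, z_extra_f]),
        cfg.lfc_scale,
    )
    homology = HomologyMap(pd.DataFrame(pairs, columns=["human_id", "fish_id"]))

    label = np.where(
        is_conc & (s > 0),
        "concordant_up",
        np.where(is_conc, "concordant_down", np.where(is_disc, "discordant", "null")),
    )
    truth = pd.DataFrame({"pair_id": human_ids, "label": label, "direction_sign": s.astype(int)})
    truth.loc[truth["label"] == "null", "direction_sign"] = 0
    return human, fish, homology, truth


# ---------------------------------------------------------------------------
# factorial contrasts

FACTORIAL_CLASSES = ("diet_dependent", "mir21_dependent", "divergent", "mir21_hcd_dependent")

#: per-class signed effect template over contrasts (A, B, C, D); s = +-1
_CLASS_EFFECTS = {
    "none": (0, 0, 0, 0),
    "diet_dependent": (1, 0, 0, 1),
    "mir21_dependent": (0, 1, 1, 0),
    "divergent": (1, 0, -1, 0),
    "mir21_hcd_dependent": (0, 0, 1, 1),
}


def simulate_factorial(
    n_genes: int,
    class_fractions: dict[str, float],
    effect_mu: float = 6.0,
    seed: int = 0,
    lfc_scale: float = 1.0,
    lfc_threshold: float = 0.5,
    padj_threshold: float = 0.05,
) -> tuple[ContrastQuad, pd.DataFrame]:
    """Four-contrast factorial DE tables with planted dependency classes.

    ``class_fractions`` maps class names (any subset of
    ``FACTORIAL_CLASSES``) to fractions; the remainder of genes are noise.
    Each class plants the signed effect pattern over contrasts A-D that its
    definition requires.  The returned tables already carry significance
    calls at the given thresholds.
    """
    unknown = set(class_fractions) - set(FACTORIAL_CLASSES)
    if unknown:
        raise ValueError(f"unknown classes {sorted(unknown)}")
    fracs = np.array([class_fractions.get(c, 0.0) for c in FACTORIAL_CLASSES])
    if (fracs < 0).any() or fracs.sum() > 1:
        raise ValueError("class fractions must be non-negative and sum to <= 1")
    rng = np.random.default_rng(seed)
    edges = np.concatenate([[0.0], np.cumsum(fracs)])
    u = rng.random(n_genes)
    labels = np.full(n_genes, "none", dtype=object)
    for cls, lo, hi in zip(FACTORIAL_CLASSES, edges[:-1], edges[1:]):
        labels[(u >= lo) & (u < hi)] = cls
    s = rng.choice([-1.0, 1.0], size=n_genes)

    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    tables = {}
    for ci, cname in enumerate("ABCD"):
        tmpl = np.array([_CLASS_EFFECTS[lab][ci] for lab in labels])
        z = tmpl * s * effect_mu + rng.standard_normal(n_genes)
        t = _z_to_table(cname, gene_ids, z, lfc_scale)
        tables[cname] = call_significant(t, lfc_threshold, padj_threshold)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "label": labels,
            "direction_sign": np.where(labels == "none", 0, s).astype(int),
        }
    )
    return ContrastQuad(**tables), truth


# ---------------------------------------------------------------------------
# gene sets with a planted core


def simulate_gene_sets(
    background_n: int,
    set_sizes,
    planted_core: int,
    seed: int = 0,
) -> tuple[list[set[str]], set[str]]:
    """m gene sets over a common background sharing a planted core.

    Each set is the core plus a uniform without-replacement sample of the
    remaining background.  Returns (sets, core).
    """
    sizes = [int(s) for s in set_sizes]
    if planted_core < 0 or (sizes and planted_core > min(sizes)):
        raise ValueError("planted_core must be <= min(set_sizes)")
    if any(s > background_n for s in sizes):
        raise ValueError("set size exceeds background")
    rng = np.random.default_rng(seed)
    universe = [f"g{i:06d}" for i in range(background_n)]
    core = set(universe[:planted_core])
    rest = np.array(universe[planted_core:])
    sets = []
    for s in sizes:
        extra = rng.choice(rest, size=s - planted_core, replace=False)
        sets.append(core | set(extra.tolist()))
    return sets, core


# ---------------------------------------------------------------------------
# UTR sequences with planted seed sites

_BASES = np.array(list("ACGT"))


def simulate_utrs(
    n_seqs: int,
    length: int,
    mirna_seq: str,
    planted_sites_per_seq: int = 0,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, int]]:
    """Random 3'UTRs with exact planted 8mer seed-match sites.

    The planted motif is the reverse complement of miRNA seed positions 2-8
    followed by an A (an 8mer site); placements are non-overlapping.
    Returns (sequences keyed by UTR id, planted-site counts).
    """
    if n_seqs == 0:
        return {}, {}
    if length < 8:
        raise ValueError("UTR length must be >= 8")
    motif = reverse_complement(mirna_seq.upper().replace("U", "T")[1:8]) + "A"
    mlen = len(motif)  # 8
    if planted_sites_per_seq * mlen > length:
        raise ValueError("too many planted sites for the sequence length")
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    truth: dict[str, int] = {}
    n_slots = length // mlen
    for i in range(n_seqs):
        chars = _BASES[rng.integers(0, 4, size=length)]
        if planted_sites_per_seq:
            # non-overlapping placement on a block grid
            slots = rng.choice(n_slots, size=planted_sites_per_seq, replace=False)
            for sl in np.sort(slots):
                chars[sl * mlen : sl * mlen + mlen] = list(motif)
        uid = f"utr{i:05d}"
        seqs[uid] = "".join(chars)
        truth[uid] = int(planted_sites_per_seq)
    return seqs, truth


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=k, description="") for k, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# point patterns in a polygonal ROI


def simulate_point_pattern(
    intensity: float,
    roi_polygon,
    min_spacing: float = 0.0,
    seed: int = 0,
    mean_area_um2: float = 30.0,
    max_tries_per_point: int = 1000,
) -> pd.DataFrame:
    """2-D nucleus-like point pattern inside a polygonal ROI.

    With ``min_spacing == 0`` this is a homogeneous Poisson process of the
    given intensity (points per um^2): the count is Poisson(intensity * area)
    and locations are uniform in the polygon.  With ``min_spacing > 0`` the
    same count target is placed by simple sequential inhibition: uniform
    proposals are rejected when closer than ``min_spacing`` to an accepted
    point; exceeding ``max_tries_per_point`` consecutive rejections raises
    (the target density is unreachable at that spacing).

    Each point carries a gamma-distributed nuclear area with the given mean.
    Returns a frame with columns x_um, y_um, area_um2.
    """
    if intensity <= 0:
        raise ValueError("intensity must be positive")
    if min_spacing < 0:
        raise ValueError("min_spacing must be >= 0")
    poly = roi_polygon if isinstance(roi_polygon, Polygon) else Polygon(np.asarray(roi_polygon))
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("invalid ROI polygon")
    import shapely

    rng = np.random.default_rng(seed)
    n = int(rng.poisson(intensity * poly.area))
    minx, miny, maxx, maxy = poly.bounds
    if min_spacing == 0:
        # homogeneous Poisson: batch-rejection-sample uniform points in the
        # bounding box into the polygon (strictly inside)
        accepted = np.empty((0, 2))
        while len(accepted) < n:
            batch = max(256, int(1.5 * (n - len(accepted)) * (maxx - minx) * (maxy - miny) / poly.area))
            x = rng.uniform(minx, maxx, size=batch)
            y = rng.uniform(miny, maxy, size=batch)
            keep = shapely.contains_xy(poly, x, y)
            accepted = np.vstack([accepted, np.column_stack([x[keep], y[keep]])])
        accepted = accepted[:n]
    else:
        # simple sequential inhibition
        pts: list[tuple[float, float]] = []
        arr = np.empty((0, 2))
        while len(pts) < n:
            tries = 0
            while True:
                x = rng.uniform(minx, maxx)
                y = rng.uniform(miny, maxy)
                ok = bool(shapely.contains_xy(poly, x, y))
                if ok and len(pts):
                    ok = np.min(np.hypot(arr[:, 0] - x, arr[:, 1] - y)) >= min_spacing
                if ok:
                    break
                tries += 1
                if tries > max_tries_per_point:
                    raise RuntimeError(
                        f"could not place point {len(pts) + 1}/{n} at min_spacing="
                        f"{min_spacing}: target density unreachable"
                    )
            pts.append((x, y))
            arr = np.asarray(pts)
        accepted = arr
    areas = rng.gamma(shape=8.0, scale=mean_area_um2 / 8.0, size=n)
    df = pd.DataFrame(accepted if n else np.empty((0, 2)), columns=["x_um", "y_um"])
    df["area_um2"] = areas
    return df


# ---------------------------------------------------------------------------
# sidecar truth files


def write_truth(truth, path: str | Path) -> None:
    """JSON sidecar for any generator's truth object."""
    if isinstance(truth, pd.DataFrame):
        payload = truth.to_dict(orient="list")
    elif isinstance(truth, (set, frozenset)):
        payload = sorted(truth)
    else:
        payload = truth
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
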