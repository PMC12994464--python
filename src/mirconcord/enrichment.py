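"""Seed-site scanning and overlap/enrichment statistics.

Covers four related statistics used when comparing dysregulated gene lists:

* a miRNA seed-match scanner over 3'UTR sequences (site classes 6mer,
  7mer-A1, 7mer-m8, 8mer, per the standard target-site taxonomy);
* the 2x2 Fisher's exact test (two-sided, point-probability definition);
* a seed-site enrichment report comparing the seed-containing proportion of
  a query gene list to a genome background;
* an exact multi-set intersection test: m sets drawn independently and
  uniformly without replacement from a common background of size N; the
  distribution of the m-way intersection size is obtained by iterated
  hypergeometric convolution, and the reported p is the upper tail
  P(X >= observed) (enrichment only);
* a directional partition of the overlap of two significant gene sets
  (up/up, down/down, discordant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de_io import DETable

# ---------------------------------------------------------------------------
# seed-site scanning

_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")

#: ranked strongest-first; overlapping loci collapse to the strongest type
SITE_RANK = ("8mer", "7mer-m8", "7mer-A1", "6mer")


@dataclass(frozen=True)
class SeedSite:
    """One predicted miRNA binding site on a UTR (0-based, half-open)."""

    utr_id: str
    site_type: str
    start: int
    end: int


def _clean(seq: str, what: str) -> str:
    s = seq.upper().replace("U", "T")
    if any(c not in "ACGT" for c in s):
        raise ValueError(f"invalid character in {what} sequence")
    return s


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def scan_seed_sites(
    utr_sequence: str,
    mirna_sequence: str,
    utr_id: str = "",
) -> list[SeedSite]:
    """Find miRNA seed-match sites in a 3'UTR.

    The seed is miRNA nucleotides 2-8 (1-based from the 5' end).  A UTR
    locus matching the reverse complement of positions 2-7 is a 6mer; with a
    downstream A it is a 7mer-A1; extended to match position 8 it is a
    7mer-m8; both extensions together make an 8mer.  Each match of the core
    hexamer yields exactly one site of the strongest applicable type.
    """
    utr = _clean(utr_sequence, "UTR")
    mir = _clean(mirna_sequence, "miRNA")
    if len(mir) < 8:
        raise ValueError("miRNA must be at least 8 nucleotides")
    rc6 = reverse_complement(mir[1:7])  # seed positions 2-7
    m8_base = reverse_complement(mir[7])  # complement of seed position 8
    sites: list[SeedSite] = []
    pos = utr.find(rc6)
    while pos != -1:
        has_m8 = pos >= 1 and utr[pos - 1] == m8_base
        has_a1 = pos + 6 < len(utr) and utr[pos + 6] == "A"
        if has_m8 and has_a1:
            sites.append(SeedSite(utr_id, "8mer", pos - 1, pos + 7))
        elif has_m8:
            sites.append(SeedSite(utr_id, "7mer-m8", pos - 1, pos + 6))
        elif has_a1:
            sites.append(SeedSite(utr_id, "7mer-A1", pos, pos + 7))
        else:
            sites.append(SeedSite(utr_id, "6mer", pos, pos + 6))
        pos = utr.find(rc6, pos + 1)
    return sites


def has_seed_site(
    utr_sequence: str,
    mirna_sequence: str,
    site_types: tuple[str, ...] = ("7mer-A1", "7mer-m8", "8mer"),
) -> bool:
    """Whether a UTR carries any site of the given classes (6mer off by default)."""
    return any(s.site_type in site_types for s in scan_seed_sites(utr_sequence, mirna_sequence))


# ---------------------------------------------------------------------------
# exact tests

def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the table [[a, b], [c, d]].

    p is the sum of hypergeometric probabilities (margins fixed) of all
    tables whose point probability does not exceed the observed one.  The
    odds ratio is a*d/(b*c), infinite when b*c == 0.
    """
    cells = np.array([a, b, c, d])
    if np.any(cells < 0) or cells.dtype.kind not in "iu" and not np.all(cells == cells.astype(int)):
        raise ValueError("cells must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("Fisher's exact test undefined for a zero margin")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    odds = np.inf if b * c == 0 else (a * d) / (b * c)
    return float(odds), float(p)


@dataclass
class SetOverlapResult:
    set_sizes: tuple[int, ...]
    background_n: int
    observed: int
    expected: float
    fold_enrichment: float
    p_value: float


def intersection_distribution(set_sizes, background_n: int) -> np.ndarray:
    """Exact pmf of the m-way intersection size under independent uniform sets.

    Starting from the first set (intersection = s1 with probability 1), each
    further set of size s intersects the current y-element intersection in a
    Hypergeometric(N, y, s) number of elements; the pmf is propagated by
    convolution over y.  Returns an array over 0..min(set_sizes).
    """
    sizes = [int(s) for s in set_sizes]
    N = int(background_n)
    if N <= 0:
        raise ValueError("background_n must be positive")
    if any(s < 0 or s > N for s in sizes) or not sizes:
        raise ValueError("set sizes must lie in [0, background_n]")
    # the intersection law is symmetric in the sets; processing smallest
    # first keeps every intermediate intersection within 0..min(sizes)
    sizes = sorted(sizes)
    m = min(sizes)
    dist = np.zeros(m + 1)
    dist[sizes[0]] = 1.0
    for s in sizes[1:]:
        new = np.zeros(m + 1)
        x = np.arange(m + 1)
        for y in np.nonzero(dist > 0)[0]:
            new += dist[y] * stats.hypergeom.pmf(x, N, y, s)
        dist = new
    return dist


def multiset_exact_test(set_sizes, observed: int, background_n: int) -> SetOverlapResult:
    """Upper-tail exact test for an observed m-set intersection.

    expected = N * prod(s_i / N); fold = observed / expected;
    p = P(X >= observed) under the independent-uniform-sets model.
    """
    sizes = tuple(int(s) for s in set_sizes)
    observed = int(observed)
    if observed < 0 or observed > min(sizes):
        raise ValueError("observed must lie in [0, min(set_sizes)]")
    dist = intersection_distribution(sizes, background_n)
    N = int(background_n)
    expected = N * float(np.prod([s / N for s in sizes]))
    p = float(min(1.0, dist[observed:].sum()))
    fold = observed / expected if expected > 0 else np.inf
    return SetOverlapResult(sizes, N, observed, expected, fold, p)


def seed_enrichment(
    gene_flags,
    background_with: int,
    background_total: int,
    disjoint_background: bool = True,
) -> dict:
    """Compare a query list's seed-containing proportion to a genome background.

    ``gene_flags`` is one boolean per query gene (has a seed site or not);
    the background is summarised by ``background_with`` seed-containing genes
    out of ``background_total``.  With the default disjoint convention the
    query genes are removed from the background margin before the 2x2 test;
    set ``disjoint_background=False`` to test against the full background.
    """
    flags = np.asarray(list(gene_flags), dtype=bool)
    n = flags.size
    if n == 0:
        raise ValueError("empty query gene set")
    k = int(flags.sum())
    if not (0 <= background_with <= background_total):
        raise ValueError("background_with must lie in [0, background_total]")
    if disjoint_background:
        bw, bt = background_with - k, background_total - n
    else:
        bw, bt = background_with, background_total
    cells = (k, n - k, bw, bt - bw)
    if any(x < 0 for x in cells):
        raise ValueError(f"inconsistent counts: derived 2x2 cell negative {cells}")
    odds, p = fisher_exact_2x2(*cells)
    return {
        "n_query": n,
        "n_with_site": k,
        "proportion": k / n,
        "background_proportion": background_with / background_total,
        "odds_ratio": odds,
        "p_value": p,
    }


# ---------------------------------------------------------------------------
# directional overlap of two DE tables

@dataclass
class DirectionalOverlap:
    shared: int
    up_up: int
    down_down: int
    discordant: int
    p_value: float
    shared_ids: tuple[str, ...]


def directional_overlap(
    table_x: DETable,
    table_y: DETable,
    id_map: dict[str, str] | None = None,
) -> DirectionalOverlap:
    """Partition the genes significant in both tables by direction pair.

    ``id_map`` translates table_x feature ids into table_y's universe
    (identity when omitted).  The overlap p-value is a two-sided Fisher's
    exact test of significant-in-x against significant-in-y over the common
    tested universe.
    """
    xdf = table_x.df.set_index("feature_id")
    ydf = table_y.df.set_index("feature_id")
    for name, df in (("x", xdf), ("y", ydf)):
        if "significant" not in df.columns:
            raise ValueError(f"table {name} lacks significance calls")
    mapper = id_map if id_map is not None else {g: g for g in xdf.index}
    common = [(gx, gy) for gx, gy in mapper.items() if gx in xdf.index and gy in ydf.index]
    if not common:
        raise ValueError("empty common universe between tables")
    sig_x = np.array([bool(xdf.at[gx, "significant"]) for gx, _ in common])
    sig_y = np.array([bool(ydf.at[_, "significant"]) for gx, _ in common])
    dir_x = np.array([xdf.at[gx, "direction"] for gx, _ in common])
    dir_y = np.array([ydf.at[gy, "direction"] for _, gy in common])
    both = sig_x & sig_y
    up_up = int(np.sum(both & (dir_x == "up") & (dir_y == "up")))
    down_down = int(np.sum(both & (dir_x == "down") & (dir_y == "down")))
    shared = int(both.sum())
    a = shared
    b = int(np.sum(sig_x & ~sig_y))
    c = int(np.sum(~sig_x & sig_y))
    d = int(np.sum(~sig_x & ~sig_y))
    try:
        _, p = fisher_exact_2x2(a, b, c, d)
    except ValueError:  # degenerate margins (e.g. nothing significant)
        p = 1.0
    return DirectionalOverlap(
        shared=shared,
        up_up=up_up,
        down_down=down_down,
        discordant=shared - up_up - down_down,
        p_value=p,
        shared_ids=tuple(gx for (gx, _), m in zip(common, both) if m),
    )


# ---------------------------------------------------------------------------
# gene-set file formats

def read_gene_set(path) -> set[str]:
    """One id per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_gmt(path) -> dict[str, set[str]]:
    """GMT-style multi-set file: name <tab> description <tab> ids..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: dict, path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            ids = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{ids}\n")
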