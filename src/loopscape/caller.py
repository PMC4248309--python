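"""Interaction calling against a distance-matched rewired (DMR) null.

Random ligation between loci on the same chromosome happens at a rate that
decays with genomic distance, so raw PET counts cannot be compared across
distances.  The caller therefore builds a control data set by *rewiring*:
every anchored PET is re-assigned to a random same-chromosome anchor pair
whose midpoint separation falls in the same logarithmic distance bin as the
PET's observed separation.  By construction the rewired data set retains
the per-bin distribution of PET distances (asserted on every run).

For every anchor pair the observed PET count is converted to a local
Z-score against the mean and standard deviation of rewired pair counts in
the pair's distance bin, where the averaging universe is *all*
same-chromosome anchor pairs in the bin (structural zeros included).
Z-scores are computed for both the observed and the rewired data sets; the
empirical FDR of a Z threshold is the ratio of rewired to observed pairs
passing it, and calls are emitted at the most permissive threshold whose
ratio stays within the user's FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from loopscape.config import CallerConfig
from loopscape.pets import AnchorSet


# ---------------------------------------------------------------------------
# distance bins
# ---------------------------------------------------------------------------

def distance_bins(distances: np.ndarray, n_bins_per_octave: int = 1) -> np.ndarray:
    """Log2-spaced bin edges covering every observed PET distance.

    Edges double every ``1 / n_bins_per_octave`` octaves, starting at the
    smallest observed distance (floored at 1 bp).
    """
    d = np.asarray(distances)
    if len(d) == 0:
        return np.array([1.0, 2.0])
    lo = max(1.0, float(d.min()))
    hi = float(d.max()) + 1.0
    n_octaves = np.log2(hi / lo)
    n_edges = int(np.ceil(n_octaves * n_bins_per_octave)) + 1
    edges = lo * 2.0 ** (np.arange(n_edges + 1) / n_bins_per_octave)
    edges[-1] = max(edges[-1], hi)
    return edges


def bin_of(distances: np.ndarray, edges: np.ndarray) -> np.ndarray:
    b = np.searchsorted(edges, np.asarray(distances), side="right") - 1
    return np.clip(b, 0, len(edges) - 2)


# ---------------------------------------------------------------------------
# pair counting
# ---------------------------------------------------------------------------

def count_pairs(anchored: pd.DataFrame) -> pd.DataFrame:
    """One row per unordered anchor pair with >= 1 PET.

    Returns columns (anchor1, anchor2, chrom, n_pets, distance).
    """
    if len(anchored) == 0:
        return pd.DataFrame(columns=["anchor1", "anchor2", "chrom", "n_pets", "distance"])
    g = (anchored.groupby(["anchor1", "anchor2", "chrom"], sort=True)
         .agg(n_pets=("name", "size"), distance=("distance", "first"))
         .reset_index())
    return g[["anchor1", "anchor2", "chrom", "n_pets", "distance"]]


def _chrom_mids(anchors: AnchorSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per chromosome: (sorted anchor midpoints, matching anchor ids)."""
    out = {}
    a = anchors.anchors
    mids = anchors.midpoints.to_numpy()
    for chrom, sub in a.groupby("chrom", sort=False):
        m = mids[sub.index.to_numpy()]
        order = np.argsort(m, kind="stable")
        out[chrom] = (m[order], sub["id"].to_numpy()[order])
    return out


def pair_universe_per_bin(anchors: AnchorSet, edges: np.ndarray) -> np.ndarray:
    """Number of same-chromosome anchor pairs whose midpoint separation falls
    in each distance bin (summed over chromosomes)."""
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    for chrom, (m, _) in _chrom_mids(anchors).items():
        for b in range(len(edges) - 1):
            lo, hi = edges[b], edges[b + 1]
            r_lo = np.searchsorted(m, m + lo, side="left")
            r_hi = np.searchsorted(m, m + hi, side="left")
            counts[b] += int(np.sum(r_hi - r_lo))
    return counts


# ---------------------------------------------------------------------------
# rewiring
# ---------------------------------------------------------------------------

@dataclass
class DMRNull:
    """The rewired control: a PET multiset with the observed per-bin distance
    histogram, its pair counts, and the binning used."""

    rewired: pd.DataFrame          # anchor1, anchor2, chrom, distance, bin, rewire_index
    pair_counts: pd.DataFrame      # per (rewire_index, pair): n_pets, distance
    edges: np.ndarray
    n_rewires: int
    seed: int

    def distance_histogram(self) -> np.ndarray:
        h = np.zeros((self.n_rewires, len(self.edges) - 1), dtype=np.int64)
        for r, sub in self.rewired.groupby("rewire_index"):
            np.add.at(h[r], bin_of(sub["distance"].to_numpy(), self.edges), 1)
        return h


def _rewire_once(anchored: pd.DataFrame, chrom_mids: dict, edges: np.ndarray,
                 rng: np.random.Generator) -> pd.DataFrame:
    """One rewired copy of the anchored PET set.

    For each PET: draw a uniformly random anchor on the PET's chromosome,
    then a uniformly random partner among anchors whose separation from it
    falls in the PET's distance bin (left or right).  Anchors with no
    in-bin partner are redrawn; eligibility is guaranteed because the
    observed pair itself sits in the bin.
    """
    frames = []
    for chrom, sub in anchored.groupby("chrom", sort=False):
        m, ids = chrom_mids[chrom]
        if len(m) < 2:
            # nothing to rewire against; pass PETs through unchanged
            frames.append(sub[["anchor1", "anchor2", "chrom", "distance"]])
            continue
        d = sub["distance"].to_numpy()
        bins = bin_of(d, edges)
        a_out = np.empty(len(sub), dtype=np.int64)
        p_out = np.empty(len(sub), dtype=np.int64)
        for b in np.unique(bins):
            lo, hi = edges[b], edges[b + 1]
            # candidate counts for every anchor in this bin
            r_lo = np.searchsorted(m, m + lo, side="left")
            r_hi = np.searchsorted(m, m + hi, side="left")
            l_lo = np.searchsorted(m, m - hi, side="right")
            l_hi = np.searchsorted(m, m - lo, side="right")
            nl = l_hi - l_lo
            tot = (r_hi - r_lo) + nl
            eligible = np.flatnonzero(tot > 0)
            if len(eligible) == 0:
                raise AssertionError(
                    f"no same-chromosome anchor pair exists in distance bin "
                    f"[{lo:.0f}, {hi:.0f}) on {chrom}, yet a PET was observed there")
            sel = np.flatnonzero(bins == b)
            a = rng.integers(0, len(m), size=len(sel))
            bad = tot[a] == 0
            if bad.any():
                a[bad] = eligible[rng.integers(0, len(eligible), size=int(bad.sum()))]
            u = rng.integers(0, tot[a])
            left = u < nl[a]
            partner = np.where(left, l_lo[a] + u, r_lo[a] + (u - nl[a]))
            a_out[sel] = a
            p_out[sel] = partner
        lo_i = np.minimum(a_out, p_out)
        hi_i = np.maximum(a_out, p_out)
        frames.append(pd.DataFrame({
            "anchor1": ids[lo_i], "anchor2": ids[hi_i],
            "chrom": chrom, "distance": np.abs(m[p_out] - m[a_out]),
        }))
    return pd.concat(frames, ignore_index=True)


def rewire(anchored: pd.DataFrame, anchors: AnchorSet,
           config: CallerConfig | None = None,
           edges: np.ndarray | None = None) -> DMRNull:
    """Build the distance-matched rewired control data set.

    Raises if the per-bin distance histogram of any rewired copy differs
    from the observed histogram (the defining contract of the control).
    """
    config = config or CallerConfig()
    config.validate()
    if len(anchored) == 0:
        raise ValueError("anchored PET set is empty")
    if edges is None:
        edges = distance_bins(anchored["distance"].to_numpy(), config.n_bins_per_octave)
    cm = _chrom_mids(anchors)
    rng = config.rng("rewire")
    copies = []
    for r in range(config.n_rewires):
        rew = _rewire_once(anchored, cm, edges, rng)
        rew["rewire_index"] = r
        copies.append(rew)
    rewired = pd.concat(copies, ignore_index=True)

    obs_hist = np.bincount(bin_of(anchored["distance"].to_numpy(), edges),
                           minlength=len(edges) - 1)
    null = DMRNull(rewired=rewired, pair_counts=pd.DataFrame(), edges=edges,
                   n_rewires=config.n_rewires, seed=config.seed)
    for r, h in enumerate(null.distance_histogram()):
        if not np.array_equal(h, obs_hist):
            raise AssertionError(
                f"rewired copy {r} does not match the observed distance histogram")

    pc = (rewired.groupby(["rewire_index", "anchor1", "anchor2", "chrom"], sort=True)
          .agg(n_pets=("distance", "size"), distance=("distance", "first"))
          .reset_index())
    null.pair_counts = pc
    return null


# ---------------------------------------------------------------------------
# local Z-scores
# ---------------------------------------------------------------------------

def _bin_stats(null: DMRNull, anchors: AnchorSet, config: CallerConfig,
               edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin mean and SD of rewired pair counts over the same-chromosome
    pair universe (structural zeros included), pooled with neighbouring bins
    where the universe is sparse."""
    nb = len(edges) - 1
    n_pairs = pair_universe_per_bin(anchors, edges).astype(float)
    pc = null.pair_counts
    b_pc = bin_of(pc["distance"].to_numpy(), edges)
    k = pc["n_pets"].to_numpy(dtype=float)
    S = np.zeros(nb)
    SS = np.zeros(nb)
    nz = np.zeros(nb)  # rewired pairs with >= 1 PET, across all rewires
    np.add.at(S, b_pc, k)
    np.add.at(SS, b_pc, k * k)
    np.add.at(nz, b_pc, 1.0)

    universe = n_pairs * null.n_rewires
    if not config.include_structural_zeros:
        universe = nz

    mu = np.zeros(nb)
    sd = np.zeros(nb)
    for b in range(nb):
        w = 0
        while True:
            lo, hi = max(0, b - w), min(nb, b + w + 1)
            U = universe[lo:hi].sum()
            if U >= config.min_pairs_per_bin or (lo == 0 and hi == nb):
                break
            w += 1
        U = max(U, 1.0)
        s, ss = S[lo:hi].sum(), SS[lo:hi].sum()
        mu[b] = s / U
        var = ss / U - mu[b] ** 2
        sd[b] = np.sqrt(max(var, 0.0))
    return mu, sd


def local_z(obs_pairs: pd.DataFrame, null: DMRNull, anchors: AnchorSet,
            config: CallerConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score observed and rewired pair counts against the local null.

    z = (n - mu_b) / max(sigma_b, sd_floor) where mu_b, sigma_b are the
    rewired-count mean/SD over all same-chromosome anchor pairs in the
    pair's distance bin.  Returns (observed pairs with z, rewired pairs
    with z).
    """
    config = config or CallerConfig()
    edges = null.edges
    mu, sd = _bin_stats(null, anchors, config, edges)
    denom = np.maximum(sd, config.sd_floor)

    def attach(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        if len(df) == 0:
            df["z"] = np.array([], dtype=float)
            return df
        b = bin_of(df["distance"].to_numpy(), edges)
        df["z"] = (df["n_pets"].to_numpy(dtype=float) - mu[b]) / denom[b]
        return df

    return attach(obs_pairs), attach(null.pair_counts)


# ---------------------------------------------------------------------------
# empirical FDR thresholding
# ---------------------------------------------------------------------------

def empirical_fdr_curve(z_obs: np.ndarray, z_rew: np.ndarray,
                        n_rewires: int = 1) -> pd.DataFrame:
    """Empirical FDR at every candidate threshold (each distinct observed z)."""
    zo = np.sort(np.asarray(z_obs, dtype=float))
    zr = np.sort(np.asarray(z_rew, dtype=float))
    cand = np.unique(zo)
    n_obs_ge = len(zo) - np.searchsorted(zo, cand, side="left")
    n_rew_ge = len(zr) - np.searchsorted(zr, cand, side="left")
    ratio = (n_rew_ge / n_rewires) / np.maximum(n_obs_ge, 1)
    return pd.DataFrame({"threshold": cand, "n_obs": n_obs_ge,
                         "n_rew": n_rew_ge, "fdr": ratio})


def call_at_fdr(z_obs_pairs: pd.DataFrame, z_rew_pairs: pd.DataFrame,
                config: CallerConfig | None = None) -> tuple[float, pd.DataFrame]:
    """Pick the most permissive Z threshold controlling the empirical FDR.

    The threshold is the smallest observed z value at which the ratio
    (# rewired pairs passing / n_rewires) / (# observed pairs passing)
    drops to or below ``config.fdr``.  Ties at the threshold are called.
    If no threshold qualifies, nothing is called.
    """
    config = config or CallerConfig()
    config.validate()
    calls = z_obs_pairs.copy()
    if len(calls) == 0:
        calls["passed"] = np.array([], dtype=bool)
        return float("inf"), calls
    curve = empirical_fdr_curve(calls["z"].to_numpy(),
                                z_rew_pairs["z"].to_numpy() if len(z_rew_pairs) else np.array([]),
                                config.n_rewires)
    ok = curve.loc[curve["fdr"] <= config.fdr]
    if len(ok) == 0:
        calls["passed"] = False
        return float("inf"), calls
    threshold = float(ok["threshold"].iloc[0])
    calls["passed"] = calls["z"] >= threshold
    return threshold, calls


def call_interactions(anchored: pd.DataFrame, anchors: AnchorSet,
                      config: CallerConfig | None = None,
                      source_dataset: str = "") -> dict:
    """End-to-end calling: count pairs, rewire, Z-score, threshold.

    Returns a dict with keys ``calls`` (all observed pairs with n_pets, z,
    passed, and anchor coordinates), ``threshold``, ``null``,
    ``rewired_z`` and ``empirical_fdr`` (the realized ratio at the emitted
    threshold).
    """
    config = config or CallerConfig()
    obs = count_pairs(anchored)
    null = rewire(anchored, anchors, config)
    z_obs, z_rew = local_z(obs, null, anchors, config)
    threshold, calls = call_at_fdr(z_obs, z_rew, config)

    n_obs_pass = int(calls["passed"].sum())
    n_rew_pass = int((z_rew["z"] >= threshold).sum()) if np.isfinite(threshold) else 0
    efdr = (n_rew_pass / config.n_rewires) / n_obs_pass if n_obs_pass else 0.0

    coords = anchors.coords_by_id()
    for side in ("1", "2"):
        key = calls[f"anchor{side}"]
        calls[f"start{side}"] = coords.loc[key, "start"].to_numpy() if len(calls) else []
        calls[f"end{side}"] = coords.loc[key, "end"].to_numpy() if len(calls) else []
    calls["source_dataset"] = source_dataset
    return {"calls": calls, "threshold": threshold, "null": null,
            "rewired_z": z_rew, "empirical_fdr": efdr}


# ---------------------------------------------------------------------------
# merging call sets across factors
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n):
        self.p = list(range(n))

    def find(self, x):
        while self.p[x] != x:
            self.p[x] = self.p[self.p[x]]
            x = self.p[x]
        return x

    def union(self, x, y):
        self.p[self.find(x)] = self.find(y)


def merge_datasets(calls_by_factor: dict[str, pd.DataFrame],
                   passed_only: bool = True) -> pd.DataFrame:
    """Equate interactions across factor data sets by reciprocal anchor overlap.

    Two calls merge when their anchor-1 peak intervals overlap and their
    anchor-2 peak intervals overlap (any-overlap, original peak
    coordinates); merged components list their supporting factors, and an
    interaction found by exactly one factor is flagged specific.
    """
    rows = []
    for factor, df in calls_by_factor.items():
        sub = df.loc[df["passed"]] if (passed_only and "passed" in df) else df
        for _, r in sub.iterrows():
            rows.append((factor, r["chrom"], int(r["start1"]), int(r["end1"]),
                         int(r["start2"]), int(r["end2"]),
                         int(r["n_pets"]) if "n_pets" in r else 1,
                         float(r["z"]) if "z" in r else np.nan))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start1", "end1", "start2", "end2",
                                     "factors", "n_factors", "specific"])
    flat = pd.DataFrame(rows, columns=["factor", "chrom", "start1", "end1",
                                       "start2", "end2", "n_pets", "z"])
    uf = _UnionFind(len(flat))
    for chrom, sub in flat.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        s1, e1 = sub["start1"].to_numpy(), sub["end1"].to_numpy()
        s2, e2 = sub["start2"].to_numpy(), sub["end2"].to_numpy()
        order = np.argsort(s1, kind="stable")
        for ii in range(len(order)):
            i = order[ii]
            for jj in range(ii + 1, len(order)):
                j = order[jj]
                if s1[j] >= e1[i]:
                    break
                if min(e2[i], e2[j]) > max(s2[i], s2[j]):
                    uf.union(int(idx[i]), int(idx[j]))
    comp = np.array([uf.find(i) for i in range(len(flat))])
    flat["component"] = comp
    merged = (flat.groupby("component")
              .agg(chrom=("chrom", "first"),
                   start1=("start1", "min"), end1=("end1", "max"),
                   start2=("start2", "min"), end2=("end2", "max"),
                   n_pets=("n_pets", "sum"), z=("z", "max"),
                   factors=("factor", lambda f: ",".join(sorted(set(f)))))
              .reset_index(drop=True))
    merged["n_factors"] = merged["factors"].str.split(",").str.len()
    merged["specific"] = merged["n_factors"] == 1
    return merged.sort_values(["chrom", "start1", "start2"]).reset_index(drop=True)
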