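"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates a ChIA-PET experiment at desk scale: binding peaks
placed over a small genome, planted true loops between peak pairs whose PET
counts are Poisson, and a background of random-ligation PETs whose genomic
distance follows a truncated power law p(d) ~ d**(-alpha) — the
heavy-tailed decay of contact frequency with distance along the DNA fibre.
Library artifacts (exact-coordinate duplicates, short convergent
self-circularization PETs) are injected at configurable rates.  Companion
tracks (DHS, chromatin states, TADs, 5C pairs, TF peak sets, HOT regions,
histone coverage, genes, expression, GO annotations) are generated with
planted relationships so every downstream stage has recoverable signal.

All randomness flows from ``SimConfig.seed`` through named substreams, so
every output is byte-identical across runs with the same configuration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from loopscape.config import SimConfig
from loopscape.pets import AnchorSet, PET_COLS, canonicalize

STATE_LABELS = ["TSS", "E", "WE", "T", "CTCF", "R"]

DEFAULT_FACTORS = ["RAD21", "CTCF", "ZNF143", "SMC3", "EP300", "TEAD4", "FOS", "GATA2"]
#: Factors planted to co-occur at loop anchors (architectural proteins).
ARCHITECTURAL_FACTORS = ["RAD21", "CTCF", "ZNF143", "SMC3"]

DEFAULT_MARKS = ["H3K4me1", "H3K4me2", "H3K4me3", "H3K27ac", "H3K36me3", "H3K27me3"]


def _power_law_sample(rng: np.random.Generator, n: int, alpha: float,
                      dmin: float, dmax: float) -> np.ndarray:
    """Inverse-CDF draws from p(d) ~ d**(-alpha) truncated to [dmin, dmax]."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        d = dmin * (dmax / dmin) ** u
    else:
        b = 1.0 - alpha
        d = (dmin ** b + u * (dmax ** b - dmin ** b)) ** (1.0 / b)
    return d


def simulate_peaks(config: SimConfig) -> AnchorSet:
    """Place non-overlapping binding peaks uniformly over the genome.

    Peaks are allocated to chromosomes proportionally to length and placed
    by the classic spacing construction (sorted uniforms in the reduced
    coordinate space), which guarantees pairwise gaps of at least 1 bp.
    """
    config.validate()
    rng = config.rng("peaks")
    w = config.peak_width_bp
    lengths = np.array([l for _, l in config.genome], dtype=float)
    quota = config.n_peaks * lengths / lengths.sum()
    n_per = np.floor(quota).astype(int)
    rem = config.n_peaks - n_per.sum()
    if rem > 0:
        frac_order = np.argsort(-(quota - n_per), kind="stable")
        n_per[frac_order[:rem]] += 1

    rows = []
    for (chrom, length), n_i in zip(config.genome, n_per):
        if n_i == 0:
            continue
        required = n_i * (w + 1)
        if required > length:
            raise ValueError(
                f"genome too small: {chrom} ({length} bp) needs {required} bp "
                f"for {n_i} non-overlapping peaks of {w} bp")
        slack = length - required
        offsets = np.sort(rng.integers(0, slack + 1, size=n_i))
        starts = offsets + np.arange(n_i) * (w + 1)
        for s in starts:
            rows.append((chrom, int(s), int(s) + w))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    df["id"] = [f"P{i:06d}" for i in range(len(df))]
    return AnchorSet(df)


def make_loop_truth(peaks: AnchorSet, config: SimConfig,
                    n_loops: int | None = None,
                    label: str = "shared",
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample planted true loops: distinct same-chromosome anchor pairs with
    midpoint distance inside [min_distance_bp, max_distance_bp].

    Returns columns (anchor1, anchor2, label, intensity).
    """
    n_loops = config.n_true_loops if n_loops is None else n_loops
    rng = rng or config.rng("truth")
    a = peaks.anchors
    mids = peaks.midpoints.to_numpy()
    candidates = []
    for chrom, sub in a.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        m = mids[idx]
        for i in range(len(idx)):
            d = np.abs(m - m[i])
            ok = np.flatnonzero((d >= config.min_distance_bp) & (d <= config.max_distance_bp)
                                & (np.arange(len(idx)) > i))
            for j in ok:
                candidates.append((idx[i], idx[j]))
    if n_loops > len(candidates):
        raise ValueError(f"cannot plant {n_loops} loops: only {len(candidates)} eligible pairs")
    chosen = rng.choice(len(candidates), size=n_loops, replace=False)
    ids = a["id"].to_numpy()
    rows = [(ids[candidates[k][0]], ids[candidates[k][1]], label, config.loop_pet_rate)
            for k in sorted(chosen)]
    return pd.DataFrame(rows, columns=["anchor1", "anchor2", "label", "intensity"])


def _reads_from_midpoints(chrom, m1, m2, s1, s2, names, read_len, chrom_len):
    half = read_len // 2
    m1 = np.clip(m1, half, chrom_len - half)
    m2 = np.clip(m2, half, chrom_len - half)
    return pd.DataFrame({
        "chrom1": chrom, "start1": m1 - half, "end1": m1 + half, "strand1": s1,
        "chrom2": chrom, "start2": m2 - half, "end2": m2 + half, "strand2": s2,
        "name": names,
    })


def simulate_pets(peaks: AnchorSet, truth: pd.DataFrame | None,
                  config: SimConfig,
                  rng: np.random.Generator | None = None,
                  intensity_scale: float = 1.0,
                  name_prefix: str = "") -> pd.DataFrame:
    """Generate a BEDPE-like PET table: planted loops + background + artifacts.

    Background PETs start at a random peak (mate-1 midpoint uniform within
    the peak plus Gaussian displacement), jump a distance drawn from the
    truncated power law in a random direction.  Loop PETs are Poisson per
    planted pair with both mates uniform inside the two anchors.
    Duplicates (exact coordinate copies) and self-circularization PETs
    (both mates inside one peak, convergent, span < peak width) are then
    injected at their configured rates.
    """
    config.validate()
    rng = rng or config.rng("pets")
    a = peaks.anchors
    chrom_len = dict(config.genome)
    coords = a.set_index("id")
    frames = []

    # planted loops
    if truth is not None and len(truth):
        missing = set(truth["anchor1"]).union(truth["anchor2"]) - set(a["id"])
        if missing:
            raise ValueError(f"truth references missing anchors: {sorted(missing)[:5]}")
        for _, row in truth.iterrows():
            lam = float(row.get("intensity", config.loop_pet_rate)) * intensity_scale
            n = rng.poisson(lam)
            if n == 0:
                continue
            c1 = coords.loc[row["anchor1"]]
            c2 = coords.loc[row["anchor2"]]
            m1 = rng.integers(c1["start"], c1["end"], size=n)
            m2 = rng.integers(c2["start"], c2["end"], size=n)
            s1 = np.where(rng.random(n) < 0.5, "+", "-")
            s2 = np.where(rng.random(n) < 0.5, "+", "-")
            names = [f"{name_prefix}loop_{row['anchor1']}_{row['anchor2']}_{k}" for k in range(n)]
            frames.append(_reads_from_midpoints(c1["chrom"], m1, m2, s1, s2, names,
                                                config.read_len_bp, chrom_len[c1["chrom"]]))

    # background with power-law distance decay
    n_bg = config.n_background_pets
    if n_bg > 0:
        pk = rng.integers(0, len(a), size=n_bg)
        starts = a["start"].to_numpy()[pk]
        ends = a["end"].to_numpy()[pk]
        chroms = a["chrom"].to_numpy()[pk]
        m1 = rng.integers(starts, ends) + rng.normal(0, 300, size=n_bg).astype(np.int64)
        d = np.round(_power_law_sample(rng, n_bg, config.decay_alpha,
                                       config.min_distance_bp, config.max_distance_bp)).astype(np.int64)
        lens = np.array([chrom_len[c] for c in chroms], dtype=np.int64)
        m1 = np.clip(m1, 0, lens - 1)
        sign = np.where(rng.random(n_bg) < 0.5, 1, -1)
        m2 = m1 + sign * d
        flip = (m2 < 0) | (m2 >= lens)
        m2[flip] = m1[flip] - sign[flip] * d[flip]
        m2 = np.clip(m2, 0, lens - 1)
        s1 = np.where(rng.random(n_bg) < 0.5, "+", "-")
        s2 = np.where(rng.random(n_bg) < 0.5, "+", "-")
        names = [f"{name_prefix}bg_{k}" for k in range(n_bg)]
        frames.append(pd.DataFrame({
            "chrom1": chroms, "start1": m1 - config.read_len_bp // 2,
            "end1": m1 + config.read_len_bp // 2, "strand1": s1,
            "chrom2": chroms, "start2": m2 - config.read_len_bp // 2,
            "end2": m2 + config.read_len_bp // 2, "strand2": s2,
            "name": names,
        }))

    pets = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=PET_COLS)
    for col in ("start1", "start2"):
        if len(pets):
            shift = np.minimum(pets[col], 0)
            end = "end1" if col == "start1" else "end2"
            pets[col] = pets[col] - shift
            pets[end] = pets[end] - shift

    # self-circularization artifacts: one peak, convergent, span < peak width
    n_sc = int(round(config.self_circ_rate * len(pets)))
    if n_sc > 0 and len(a):
        pk = rng.integers(0, len(a), size=n_sc)
        starts = a["start"].to_numpy()[pk]
        chroms = a["chrom"].to_numpy()[pk]
        w = config.peak_width_bp
        span = rng.integers(config.read_len_bp, max(config.read_len_bp + 1, w - 1), size=n_sc)
        m1 = starts + rng.integers(0, np.maximum(1, w - span))
        m2 = m1 + span
        names = [f"{name_prefix}sc_{k}" for k in range(n_sc)]
        lens = np.array([chrom_len[c] for c in chroms], dtype=np.int64)
        frames.append(_reads_from_midpoints(chroms, m1, m2,
                                            np.repeat("+", n_sc), np.repeat("-", n_sc),
                                            names, config.read_len_bp, int(lens.min())))
        pets = pd.concat([pets, frames[-1]], ignore_index=True)

    # exact-coordinate duplicates
    n_dup = int(round(config.duplicate_rate * len(pets)))
    if n_dup > 0:
        idx = rng.integers(0, len(pets), size=n_dup)
        dups = pets.iloc[idx].copy()
        dups["name"] = [f"{n}_d{k}" for k, n in enumerate(dups["name"])]
        pets = pd.concat([pets, dups], ignore_index=True)

    return canonicalize(pets[PET_COLS])


# ---------------------------------------------------------------------------
# companion tracks
# ---------------------------------------------------------------------------

def simulate_companion_tracks(config: SimConfig, peaks: AnchorSet,
                              truth: pd.DataFrame,
                              fraction_in_5c: float = 0.7,
                              n_extra_dhs: int | None = None,
                              tad_size_bp: int = 1_000_000,
                              factors: list[str] | None = None,
                              marks: list[str] | None = None,
                              n_cell_lines: int = 12,
                              focal_line: str = "cellA",
                              elevated_loop_fraction: float = 0.5,
                              expression_boost: float = 8.0) -> dict:
    """Generate every companion input the downstream analyses consume.

    Planted structure:

    * every other anchor is a promoter anchor holding a gene TSS and a TSS
      chromatin state; non-promoter anchors cycle through the remaining
      states, with loop partners of promoter anchors alternating E and R so
      the distal-state/expression analysis has recoverable signal;
    * genes whose promoter loops to an E element get ``expression_boost``-fold
      higher RPKM in the focal cell line than genes looping to R elements;
    * architectural factors (RAD21/CTCF/ZNF143/SMC3) are planted at loop
      anchors; other factors bind random anchor subsets;
    * HOT regions are anchors bound by at least four factors;
    * histone coverage is elevated inside a fraction of loops (for
      loop-domain clustering);
    * a configurable fraction of planted loops is copied into the 5C pair
      set.

    Returns a dict with keys: dhs, states, tads, fivec, fivec_tested,
    tf_peaks (dict factor -> BED frame), hot, coverage (dict mark ->
    bedGraph frame), genes, rpkm, go.
    """
    rng = config.rng("companion")
    a = peaks.anchors
    mids = peaks.midpoints.to_numpy()
    ids = a["id"].to_numpy()
    factors = factors or list(DEFAULT_FACTORS)
    marks = marks or list(DEFAULT_MARKS)
    chrom_len = dict(config.genome)

    # --- promoter anchors, genes -------------------------------------------
    promoter_mask = np.zeros(len(a), dtype=bool)
    promoter_mask[::2] = True
    id2row = {i: k for k, i in enumerate(ids)}

    # TFs are themselves genes: the first promoter genes carry the factor
    # names so TF -> TF edges (and the tier hierarchy) can exist
    n_prom = int(promoter_mask.sum())
    gene_names = (list(factors) + [f"G{k:05d}" for k in range(n_prom)])[:n_prom]
    genes = pd.DataFrame({
        "gene": gene_names,
        "chrom": a["chrom"].to_numpy()[promoter_mask],
        "tss": mids[promoter_mask],
        "strand": "+",
    })
    anchor_of_gene = ids[promoter_mask]
    gene_of_anchor = dict(zip(anchor_of_gene, genes["gene"]))

    # --- chromatin states: loop partners of promoters alternate E / R ------
    state = np.array(["" for _ in ids], dtype=object)
    state[promoter_mask] = "TSS"
    partner_state: dict[str, str] = {}
    toggle = 0
    for _, row in truth.iterrows():
        x, y = row["anchor1"], row["anchor2"]
        for prom, dist in ((x, y), (y, x)):
            if promoter_mask[id2row[prom]] and not promoter_mask[id2row[dist]]:
                if state[id2row[dist]] == "":
                    state[id2row[dist]] = "E" if toggle % 2 == 0 else "R"
                    toggle += 1
                partner_state.setdefault(prom, state[id2row[dist]])
    cycle = ["E", "WE", "CTCF", "T", "R"]
    k = 0
    for i in range(len(ids)):
        if state[i] == "":
            state[i] = cycle[k % len(cycle)]
            k += 1

    # --- DHS: anchors plus extra open-chromatin sites -----------------------
    n_extra = len(a) // 2 if n_extra_dhs is None else n_extra_dhs
    dhs_rows = [(c, s, e) for c, s, e in zip(a["chrom"], a["start"], a["end"])]
    for _ in range(n_extra):
        chrom, length = config.genome[rng.integers(0, len(config.genome))]
        s = int(rng.integers(0, length - 500))
        dhs_rows.append((chrom, s, s + 500))
    dhs = pd.DataFrame(dhs_rows, columns=["chrom", "start", "end"])
    dhs = dhs.sort_values(["chrom", "start"]).reset_index(drop=True)
    dhs["name"] = [f"D{k:06d}" for k in range(len(dhs))]

    # --- state segmentation BED: one segment per anchor + random fillers ----
    st_rows = [(c, s, e, lab) for c, s, e, lab in zip(a["chrom"], a["start"], a["end"], state)]
    for _ in range(n_extra):
        chrom, length = config.genome[rng.integers(0, len(config.genome))]
        s = int(rng.integers(0, length - 2000))
        st_rows.append((chrom, s, s + 2000, cycle[int(rng.integers(0, len(cycle)))]))
    states = pd.DataFrame(st_rows, columns=["chrom", "start", "end", "state"])
    states = states.sort_values(["chrom", "start"]).reset_index(drop=True)

    # --- TADs tile each chromosome -----------------------------------------
    tad_rows = []
    for chrom, length in config.genome:
        edges = list(range(0, length, tad_size_bp)) + [length]
        for s, e in zip(edges[:-1], edges[1:]):
            tad_rows.append((chrom, s, e))
    tads = pd.DataFrame(tad_rows, columns=["chrom", "start", "end"])
    tads["name"] = [f"TAD{k:04d}" for k in range(len(tads))]

    # --- 5C pairs -----------------------------------------------------------
    n_in = int(round(fraction_in_5c * len(truth)))
    in_idx = rng.choice(len(truth), size=n_in, replace=False) if n_in else np.array([], int)
    coords = a.set_index("id")
    fc_rows = []
    for k in sorted(in_idx):
        r = truth.iloc[k]
        c1, c2 = coords.loc[r["anchor1"]], coords.loc[r["anchor2"]]
        fc_rows.append((c1["chrom"], c1["start"], c1["end"],
                        c2["chrom"], c2["start"], c2["end"], f"5C{k:04d}"))
    fivec = pd.DataFrame(fc_rows, columns=["chrom1", "start1", "end1",
                                           "chrom2", "start2", "end2", "name"])
    fivec_tested = pd.DataFrame(
        [(chrom, 0, length) for chrom, length in config.genome],
        columns=["chrom", "start", "end"])

    # --- TF peak sets --------------------------------------------------------
    loop_anchor_rows = sorted({id2row[x] for x in
                               pd.concat([truth["anchor1"], truth["anchor2"]])})
    tf_peaks = {}
    for f in factors:
        if f in ARCHITECTURAL_FACTORS:
            take = np.zeros(len(a), dtype=bool)
            take[loop_anchor_rows] = rng.random(len(loop_anchor_rows)) < 0.9
            take |= rng.random(len(a)) < 0.10
        else:
            take = rng.random(len(a)) < 0.30
        sub = a.loc[take, ["chrom", "start", "end"]].reset_index(drop=True)
        sub["name"] = [f"{f}_{k}" for k in range(len(sub))]
        tf_peaks[f] = sub

    # --- HOT regions: anchors bound by >= 4 factors -------------------------
    bound_count = np.zeros(len(a), dtype=int)
    for f, sub in tf_peaks.items():
        key = set(zip(sub["chrom"], sub["start"]))
        bound_count += np.array([(c, s) in key for c, s in zip(a["chrom"], a["start"])])
    hot = a.loc[bound_count >= 4, ["chrom", "start", "end"]].reset_index(drop=True)
    hot["name"] = [f"HOT{k:04d}" for k in range(len(hot))]

    # --- histone coverage: elevated inside a subset of loops ----------------
    n_elev = int(round(elevated_loop_fraction * len(truth)))
    elev_idx = sorted(rng.choice(len(truth), size=n_elev, replace=False)) if n_elev else []
    elev_regions = []
    for k in elev_idx:
        r = truth.iloc[k]
        c1, c2 = coords.loc[r["anchor1"]], coords.loc[r["anchor2"]]
        elev_regions.append((c1["chrom"], int(c1["end"]), int(c2["start"])))
    coverage = {}
    for mi, mark in enumerate(marks):
        rows = []
        for chrom, length in config.genome:
            cuts = sorted({0, length} | {
                p for c, s, e in elev_regions if c == chrom for p in (s, e)})
            for s, e in zip(cuts[:-1], cuts[1:]):
                inside = any(c == chrom and s >= rs and e <= re
                             for c, rs, re in elev_regions)
                base = 1.0 + 0.1 * mi
                rows.append((chrom, s, e, base * (5.0 if inside else 1.0)))
        coverage[mark] = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])

    # --- expression: E-looped genes boosted in the focal line ----------------
    lines = [focal_line] + [f"cell{chr(ord('B') + k)}" for k in range(n_cell_lines - 1)]
    base_expr = rng.lognormal(mean=1.0, sigma=0.5, size=(len(genes), n_cell_lines))
    rpkm = pd.DataFrame(base_expr, columns=lines)
    rpkm.insert(0, "gene", genes["gene"])
    for anchor, g in gene_of_anchor.items():
        st = partner_state.get(anchor)
        if st == "E":
            rpkm.loc[rpkm["gene"] == g, focal_line] *= expression_boost
        elif st == "R":
            rpkm.loc[rpkm["gene"] == g, focal_line] *= 1.0 / expression_boost

    # --- GO annotations ------------------------------------------------------
    terms = [f"GO:{k:07d}" for k in range(8)]
    go_rows = []
    e_genes = {gene_of_anchor[x] for x, s in partner_state.items() if s == "E"
               if x in gene_of_anchor}
    for g in genes["gene"]:
        if g in e_genes:
            go_rows.append((g, terms[0]))  # planted term for E-looped genes
        for t in rng.choice(terms[1:], size=2, replace=False):
            go_rows.append((g, t))
    go = pd.DataFrame(go_rows, columns=["gene", "term"])

    return {
        "dhs": dhs, "states": states, "tads": tads,
        "fivec": fivec, "fivec_tested": fivec_tested,
        "tf_peaks": tf_peaks, "hot": hot, "coverage": coverage,
        "genes": genes, "rpkm": rpkm, "go": go,
        "anchor_state": pd.DataFrame({"id": ids, "state": state}),
    }


def simulate_two_conditions(config: SimConfig, peaks: AnchorSet,
                            n_shared: int = 200,
                            n_specific_a: int = 50,
                            n_specific_b: int = 0,
                            fold_change: float = 4.0,
                            rad21_diff_fraction: float = 0.1,
                            ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                                       pd.DataFrame, pd.DataFrame]:
    """Two-condition experiment: shared loops, condition-specific loops with a
    fold-change excess, and RAD21 peak sets differing at a fraction of anchors.

    Shared loops have equal expected PET counts in A and B; an A-specific
    loop has ``fold_change`` times the base rate in A and the base rate in
    B (so the mean count ratio is the fold change).  RAD21 binding is lost
    in one condition at ``rad21_diff_fraction`` of anchors not involved in
    specific loops, exercising the binding-control path of the
    differential caller.

    Returns (pets_A, pets_B, truth, rad21_A, rad21_B).
    """
    n_specific = n_specific_a + n_specific_b
    if n_specific > 0 and fold_change < 1.0:
        raise ValueError("fold_change must be >= 1 for condition-specific loops")
    rng = config.rng("two_conditions")
    total = n_shared + n_specific
    truth = make_loop_truth(peaks, config, n_loops=total, rng=rng)
    labels = np.array(["shared"] * n_shared + ["A"] * n_specific_a + ["B"] * n_specific_b)
    rng.shuffle(labels)
    if fold_change == 1.0:
        labels[:] = "shared"
    truth = truth.assign(label=labels)

    base = config.loop_pet_rate
    truth_a = truth.assign(intensity=np.where(truth["label"] == "A", base * fold_change, base))
    truth_b = truth.assign(intensity=np.where(truth["label"] == "B", base * fold_change, base))
    pets_a = simulate_pets(peaks, truth_a, config, rng=config.rng("pets_A"), name_prefix="A_")
    pets_b = simulate_pets(peaks, truth_b, config, rng=config.rng("pets_B"), name_prefix="B_")

    # RAD21: bound at every anchor except a lost fraction in condition B
    a = peaks.anchors
    specific_anchors = set(truth.loc[truth["label"] != "shared", "anchor1"]) | \
        set(truth.loc[truth["label"] != "shared", "anchor2"])
    eligible = np.flatnonzero(~a["id"].isin(specific_anchors).to_numpy())
    n_lost = int(round(rad21_diff_fraction * len(eligible)))
    lost = set(rng.choice(eligible, size=n_lost, replace=False)) if n_lost else set()
    rad21_a = a[["chrom", "start", "end", "id"]].copy()
    keep_b = np.array([k not in lost for k in range(len(a))])
    rad21_b = a.loc[keep_b, ["chrom", "start", "end", "id"]].reset_index(drop=True)
    return pets_a, pets_b, truth, rad21_a, rad21_b
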