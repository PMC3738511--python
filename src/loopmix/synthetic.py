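"""Simulated loop-design two-color experiments with known ground truth.

The generator reproduces the structure of a 12-plex two-channel experiment:
samples are laid out in a balanced dye-swap pairing (an 8-sample group gets
4 Cy3 and 4 Cy5 channels), every transcript is printed as duplicate spots
assigned to layout blocks, and the log2 signal is built from exactly the
terms the two analysis models decompose:

    baseline + transcript offset + treatment effect (DE transcripts only)
    + dye + block + array + array:dye + array:block + residual

with the array terms drawn as independent Normal components.  Intensities
are 2^signal, so the log2 transform recovers the additive scale exactly.
Missingness is injected completely at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_design import (INTENSITY_COLUMNS, AnnotationMap, ArrayDesign,
                        IntensityMatrix)


@dataclass
class EffectSpec:
    """Generating parameters for one simulated experiment.

    Defaults emulate the founding-queen study conditions at desk scale:
    three treatment groups of eight samples on twelve two-channel arrays,
    duplicate spots per transcript, a log2 dye offset of 1, and array-level
    random components comparable to the residual scale.
    """

    n_transcripts: int = 200
    duplicate_spots: int = 2
    groups: list = field(default_factory=lambda: [
        ("haplo", 8), ("win", 8), ("los", 8)])
    fraction_de: float = 0.1
    treatment_effect_sd: float = 1.0
    dye_effect: float = 1.0
    block_effects: list = field(default_factory=lambda: [0.0, 0.3, -0.2, 0.1])
    sd_array: float = 0.5
    sd_array_dye: float = 0.3
    sd_array_block: float = 0.2
    sd_residual: float = 0.25
    sd_transcript: float = 1.0
    baseline_mean: float = 10.0
    missing_rate: float = 0.0
    seed: int = 0
    plex: int = 12

    def __post_init__(self) -> None:
        if not (0 <= self.fraction_de <= 1):
            raise ValueError("fraction_de must be in [0, 1]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        for name in ("treatment_effect_sd", "sd_array", "sd_array_dye",
                     "sd_array_block", "sd_residual", "sd_transcript"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SyntheticTruth:
    de_transcripts: set
    group_effects: pd.DataFrame        # transcript x non-reference groups
    realized_components: dict          # sample variances of the drawn terms
    design: ArrayDesign
    spec: EffectSpec


def make_loop_design(groups, plex: int = 12, dye_swap_balance: bool = True,
                     spots: pd.DataFrame | None = None) -> ArrayDesign:
    """Lay out samples on two-channel arrays with balanced dye swaps.

    Samples are ordered by group then index and filled into channel slots
    (array 1 Cy3, array 1 Cy5, array 2 Cy3, ...), so consecutive samples
    share an array with opposite dyes and every even-sized group receives
    half of each dye.  An odd total leaves the last Cy5 channel unused.
    """
    groups = list(groups)
    total = sum(n for _, n in groups)
    if total > 2 * plex:
        raise ValueError(f"{total} samples exceed 2x{plex} channels")
    # Round-robin over groups so consecutive samples — and hence the two
    # channels of each array — mix treatment groups, as a hybridization loop
    # does; nesting treatment inside arrays would leave group contrasts
    # confounded with the array random effect.
    ordered = []  # (sample, group)
    pools = [[(f"{label}_{i:02d}", label) for i in range(1, n + 1)]
             for label, n in groups]
    idx = 0
    while any(pools):
        pool = pools[idx % len(pools)]
        if pool:
            ordered.append(pool.pop(0))
        idx += 1

    # Pair consecutive samples onto arrays, then orient each pair's dyes
    # greedily toward per-group Cy3/Cy5 balance (4/4 for 8-sample groups).
    cy3_count = {label: 0 for label, _ in groups}
    n_seen = {label: 0 for label, _ in groups}
    rows = []
    for pair_i in range(0, total, 2):
        array_id = f"a{pair_i // 2 + 1:02d}"
        members = ordered[pair_i:pair_i + 2]
        dye_order = ("Cy3", "Cy5")
        if len(members) == 2 and dye_swap_balance:
            (s_a, g_a), (s_b, g_b) = members
            bal_a = cy3_count[g_a] - n_seen[g_a] / 2
            bal_b = cy3_count[g_b] - n_seen[g_b] / 2
            first_cy3 = bal_a <= bal_b  # give Cy3 to the group shorter on it
            members = members if first_cy3 else members[::-1]
        elif len(members) == 1 and dye_swap_balance:
            g = members[0][1]  # odd total: the lone channel takes whichever
            if cy3_count[g] >= (n_seen[g] + 1) / 2:  # dye balances its group
                dye_order = ("Cy5",)
        for dye, (sample, group) in zip(dye_order, members):
            rows.append({"array": array_id, "dye": dye,
                         "sample": sample, "group": group})
            if dye == "Cy3":
                cy3_count[group] += 1
            n_seen[group] += 1
    channels = pd.DataFrame(rows)
    channels = channels.sort_values(["array", "dye"]).reset_index(drop=True)
    if spots is None:
        spots = pd.DataFrame(columns=["spot", "transcript",
                                      "duplicate_index", "block"])
    return ArrayDesign(channels, spots)


def _spot_layout(spec: EffectSpec) -> pd.DataFrame:
    rows = []
    n_blocks = max(len(spec.block_effects), 1)
    for t in range(1, spec.n_transcripts + 1):
        tid = f"t{t:05d}"
        for d in range(1, spec.duplicate_spots + 1):
            # duplicate spots of a transcript land in different blocks,
            # round-robin over the layout
            block = f"b{((t + d) % n_blocks) + 1}"
            rows.append({"spot": f"{tid}.{d}", "transcript": tid,
                         "duplicate_index": d, "block": block})
    return pd.DataFrame(rows)


def generate(spec: EffectSpec) -> tuple[IntensityMatrix, ArrayDesign, SyntheticTruth]:
    """Simulate one experiment; deterministic for a fixed spec and seed."""
    rng = np.random.default_rng(spec.seed)
    spots = _spot_layout(spec)
    design = make_loop_design(spec.groups, plex=spec.plex, spots=spots)
    ch = design.channels

    n_t = spec.n_transcripts
    transcripts = [f"t{t:05d}" for t in range(1, n_t + 1)]
    n_de = round(spec.fraction_de * n_t)
    de_idx = rng.choice(n_t, size=n_de, replace=False)
    de_set = {transcripts[i] for i in sorted(de_idx)}

    group_labels = [g for g, _ in spec.groups]
    ref = group_labels[0]
    effects = pd.DataFrame(0.0, index=transcripts, columns=group_labels[1:])
    for tid in sorted(de_set):
        effects.loc[tid] = rng.normal(0.0, spec.treatment_effect_sd,
                                      size=len(group_labels) - 1)

    t_offset = rng.normal(0.0, spec.sd_transcript, size=n_t)
    offsets = dict(zip(transcripts, t_offset))

    arrays = design.arrays
    blocks = sorted(spots["block"].unique())
    block_effect = {b: spec.block_effects[i % len(spec.block_effects)]
                    if spec.block_effects else 0.0
                    for i, b in enumerate(blocks)}
    u_array = {a: rng.normal(0.0, spec.sd_array) for a in arrays}
    u_ad = {(a, d): rng.normal(0.0, spec.sd_array_dye)
            for a in arrays for d in ("Cy3", "Cy5")}
    u_ab = {(a, b): rng.normal(0.0, spec.sd_array_block)
            for a in arrays for b in blocks}

    # vectorized signal assembly: spots x channels
    n_spots = len(spots)
    n_ch = len(ch)
    spot_base = (spec.baseline_mean
                 + spots["transcript"].map(offsets).to_numpy(dtype=float)
                 + spots["block"].map(block_effect).to_numpy(dtype=float))
    eff_full = effects.copy()
    eff_full.insert(0, ref, 0.0)
    treat = eff_full.loc[spots["transcript"], ch["group"]].to_numpy(dtype=float)
    chan_term = (ch["array"].map(u_array).to_numpy(dtype=float)
                 + np.array([u_ad[(a, d)] for a, d in zip(ch["array"], ch["dye"])])
                 + np.where(ch["dye"].to_numpy() == "Cy3", spec.dye_effect, 0.0))
    ab_term = np.array([[u_ab[(a, b)] for a in ch["array"]]
                        for b in spots["block"]])
    signal = (spot_base[:, None] + chan_term[None, :] + ab_term + treat
              + rng.normal(0.0, spec.sd_residual, size=(n_spots, n_ch)))
    df = pd.DataFrame({
        "spot": np.repeat(spots["spot"].to_numpy(), n_ch),
        "array": np.tile(ch["array"].to_numpy(), n_spots),
        "dye": np.tile(ch["dye"].to_numpy(), n_spots),
        "intensity": 2.0 ** signal.ravel(),
    }, columns=INTENSITY_COLUMNS)
    if spec.missing_rate > 0:
        mask = rng.random(len(df)) < spec.missing_rate
        df.loc[mask, "intensity"] = np.nan

    realized = {
        "array": float(np.var(list(u_array.values()), ddof=1))
        if len(u_array) > 1 else 0.0,
        "array_dye": float(np.var(list(u_ad.values()), ddof=1))
        if len(u_ad) > 1 else 0.0,
        "array_block": float(np.var(list(u_ab.values()), ddof=1))
        if len(u_ab) > 1 else 0.0,
    }
    truth = SyntheticTruth(de_transcripts=de_set, group_effects=effects,
                           realized_components=realized, design=design,
                           spec=spec)
    return IntensityMatrix(df), design, truth


def generate_factor_matrix(n_genes: int = 200, n_per_cell: int = 6,
                           sd_env: float = 3.0, sd_rank: float = 1.0,
                           sd_noise: float = 0.1, seed: int = 0):
    """Samples x genes matrix with two crossed binary factors planted.

    Every gene carries an environment loading ~ N(0, sd_env) and a rank
    loading ~ N(0, sd_rank); a sample's value is half the loading signed by
    its factor levels, plus Gaussian noise.  With sd_env:sd_rank = 3:1 the
    planted environment:rank variance ratio is 9:1.  Returns
    (matrix DataFrame, labels DataFrame, truth dict with the realized
    variance shares in percent).
    """
    rng = np.random.default_rng(seed)
    env = np.repeat([1.0, 1.0, -1.0, -1.0], n_per_cell)
    rank = np.repeat([1.0, -1.0, 1.0, -1.0], n_per_cell)
    n_samples = 4 * n_per_cell
    a = rng.normal(0.0, sd_env, size=n_genes)
    b = rng.normal(0.0, sd_rank, size=n_genes)
    noise = rng.normal(0.0, sd_noise, size=(n_samples, n_genes))
    X = env[:, None] * (a / 2) + rank[:, None] * (b / 2) + noise
    samples = [f"s{i:02d}" for i in range(1, n_samples + 1)]
    genes = [f"g{j:04d}" for j in range(1, n_genes + 1)]
    labels = pd.DataFrame({
        "environment": np.where(env > 0, "single", "paired"),
        "rank": np.where(rank > 0, "winner", "loser"),
    }, index=samples)
    v_env = float(np.sum(a ** 2) / 4)
    v_rank = float(np.sum(b ** 2) / 4)
    v_noise = float(sd_noise ** 2 * n_genes)
    total = v_env + v_rank + v_noise
    truth = {"env_share_pct": 100 * v_env / total,
             "rank_share_pct": 100 * v_rank / total,
             "noise_share_pct": 100 * v_noise / total}
    return pd.DataFrame(X, index=samples, columns=genes), labels, truth


def generate_annotation(n_genes: int, n_terms: int, planted_term: str = "T001",
                        enrichment_strength: float = 5.0, seed: int = 0,
                        term_size: int = 30, query_size: int = 50,
                        n_ancestors: int = 3):
    """Random gene-term incidence with one term enriched in a query set.

    Every term annotates ``term_size`` random genes.  The query ("significant")
    gene set of size ``query_size`` is drawn with sampling odds multiplied by
    *enrichment_strength* for members of the planted term; strength 1 plants
    no signal.  Returns (AnnotationMap, query_set, planted_term).
    """
    if n_terms < 1:
        raise ValueError("need at least one term")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(1, n_genes + 1)]
    terms = [f"T{i:03d}" for i in range(1, n_terms + 1)]
    if planted_term not in terms:
        terms[0] = planted_term
    gene_terms: dict = {}
    members: dict = {}
    for term in terms:
        chosen = rng.choice(n_genes, size=min(term_size, n_genes), replace=False)
        members[term] = {genes[i] for i in chosen}
        for i in chosen:
            gene_terms.setdefault(genes[i], set()).add(term)

    weights = np.ones(n_genes)
    for i, g in enumerate(genes):
        if g in members[planted_term]:
            weights[i] *= enrichment_strength
    probs = weights / weights.sum()
    query_idx = rng.choice(n_genes, size=min(query_size, n_genes),
                           replace=False, p=probs)
    query = {genes[i] for i in query_idx}

    ancestors = [f"ANC{i}" for i in range(1, n_ancestors + 1)]
    slim = {term: {ancestors[i % n_ancestors]} for i, term in enumerate(terms)}
    annotation = AnnotationMap(gene_terms=gene_terms, slim=slim,
                               universe=set(genes))
    return annotation, query, planted_term
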