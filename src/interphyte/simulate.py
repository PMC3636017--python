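"""Synthetic mixed-species transcriptome data with known ground truth.

Every input the deconvolution pipeline consumes can be generated here: a
parasite transcript pool plus two host species at controlled nucleotide
divergence and a non-parasitic control relative, interface read libraries
contaminated with a known host fraction, orthogroup memberships and GO Slim
labels with planted region-specific enrichment, negative-binomial expression
levels, and qPCR Ct replicate tables with known fold changes.

Homolog evolution is substitution-only by default (an optional indel rate is
exposed), which keeps the expected pairwise identity analytic: identity of a
pair diverged at per-site probability ``d`` is approximately ``1 - d``.
All randomness flows from ``SimulationConfig.seed`` through per-purpose
``numpy`` generator streams, so identical configs give byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .similarity import revcomp

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

VENN_REGIONS = (
    "shared_all",
    "interface_shared",
    "A_interface_unique",
    "B_interface_unique",
    "A_above_shared",
    "B_above_shared",
    "above_unique",
)

# Default orthogroup region proportions, shaped like a generalist parasite
# whose interface transcriptome has a core shared component, substantial
# host-specific components, and a large housekeeping overlap with
# above-ground tissue.
DEFAULT_REGION_PROPORTIONS = {
    "shared_all": 0.536,
    "interface_shared": 0.101,
    "A_interface_unique": 0.061,
    "B_interface_unique": 0.033,
    "A_above_shared": 0.096,
    "B_above_shared": 0.028,
    "above_unique": 0.145,
}

DEFAULT_GOSLIM_CATEGORIES = {
    "none": 0.30,
    "metabolic process": 0.12,
    "transport": 0.10,
    "response to stress": 0.08,
    "transcription factor activity": 0.07,
    "protein binding": 0.09,
    "catalytic activity": 0.10,
    "cell wall organization": 0.05,
    "signal transduction": 0.05,
    "developmental process": 0.04,
}


@dataclass
class QpcrModel:
    """True fold changes (treatment vs control) and Ct noise structure."""

    true_fold: dict = field(
        default_factory=lambda: {"EXPB1": 120.0, "EXPA4": 0.5}
    )
    ct_noise_sd: float = 0.2
    n_bio_replicates: int = 3
    n_tech_replicates: int = 3
    reference_ct: float = 20.0
    control_delta_ct: float = 3.0
    loading_sd: float = 1.0

    def validate(self) -> None:
        if self.n_bio_replicates < 1 or self.n_tech_replicates < 1:
            raise ValueError("replicate counts must be positive")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be nonnegative")
        for g, f in self.true_fold.items():
            if f <= 0:
                raise ValueError(f"true fold for {g} must be positive")


@dataclass
class ExpressionModel:
    """Gamma-Poisson (negative binomial) per-transcript expression."""

    mean: float = 80.0
    dispersion: float = 0.25


@dataclass
class SimulationConfig:
    seed: int = 0
    # transcript pools
    n_parasite_transcripts: int = 150
    n_host_transcripts: int = 80
    n_contaminant_unigenes: int = 20
    n_nonplant_unigenes: int = 8
    n_unknown_unigenes: int = 12
    transcript_length_range: tuple = (250, 1200)
    # homolog divergence (per-site substitution probabilities)
    divergence_parasite_host: float = 0.20
    divergence_within_parasite: float = 0.02
    divergence_control: float = 0.12
    divergence_annotation: float = 0.05
    indel_rate: float = 0.0
    parasite_reference_coverage: float = 0.85
    annotation_coverage: float = 0.90
    # read library
    contamination_fraction: float = 0.10
    read_length: int = 83
    n_read_pairs: int = 2000
    insert_size_mean: float = 250.0
    insert_size_sd: float = 30.0
    base_error_rate: float = 0.004
    low_quality_tail_prob: float = 0.15
    # orthogroups / GO Slim
    n_orthogroups: int = 3000
    region_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_REGION_PROPORTIONS)
    )
    goslim_categories: dict = field(
        default_factory=lambda: dict(DEFAULT_GOSLIM_CATEGORIES)
    )
    enrichment_log_odds: dict = field(
        default_factory=lambda: {
            "A_interface_unique": {"none": 1.0},
            "B_interface_unique": {"none": 1.0},
        }
    )
    expression: ExpressionModel = field(default_factory=ExpressionModel)
    qpcr: QpcrModel = field(default_factory=QpcrModel)

    def validate(self) -> None:
        probs = [
            self.divergence_parasite_host,
            self.divergence_within_parasite,
            self.divergence_control,
            self.divergence_annotation,
            self.indel_rate,
            self.contamination_fraction,
            self.base_error_rate,
            self.parasite_reference_coverage,
            self.annotation_coverage,
            self.low_quality_tail_prob,
        ]
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.n_parasite_transcripts <= 0 or self.n_host_transcripts <= 0:
            raise ValueError("transcript counts must be positive")
        lo, hi = self.transcript_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("transcript_length_range must be positive and ordered")
        if self.read_length <= 0 or self.n_read_pairs < 0:
            raise ValueError("read dimensions must be positive")
        self.qpcr.validate()

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible generator for one simulation purpose."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class ReferenceSets:
    """Labeled transcript sets plus per-unigene ground truth."""

    parasite_assembly: dict
    parasite_reference: dict
    host_a: dict
    host_b: dict
    control: dict
    annotation_db: dict
    annotation_labels: pd.DataFrame  # subject_id, kingdom, orthogroup, goslim
    truth: pd.DataFrame  # unigene_id, origin, true_category, orthogroup, goslim, true_expression


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def mutate(seq: str, divergence: float, rng: np.random.Generator, indel_rate: float = 0.0) -> str:
    """Independent per-site substitutions at the given rate; optional indels."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < divergence
    if hit.any():
        # substitute with one of the three other bases, uniformly
        shifts = rng.integers(1, 4, size=int(hit.sum()))
        idx = np.searchsorted(BASES, arr[hit])
        arr[hit] = BASES[(idx + shifts) % 4]
    out = arr.tobytes().decode("ascii")
    if indel_rate > 0:
        chars = []
        for c in out:
            r = rng.random()
            if r < indel_rate / 2:
                continue  # deletion
            chars.append(c)
            if r > 1 - indel_rate / 2:
                chars.append("ACGT"[rng.integers(0, 4)])  # insertion
        out = "".join(chars)
    return out


def simulate_reference_sets(config: SimulationConfig) -> ReferenceSets:
    """Generate parasite/host/control transcript sets with ground truth.

    The parasite assembly pool holds parasite-derived unigenes plus planted
    host contaminants, non-plant sequences, and unannotatable sequences, so
    the downstream classification cascade can be scored against truth.
    """
    config.validate()
    rng = config.rng(0)
    lo, hi = config.transcript_length_range
    regions = list(config.region_proportions)
    region_p = np.array([config.region_proportions[r] for r in regions], dtype=float)
    region_p = region_p / region_p.sum()
    cats = list(config.goslim_categories)
    cat_p = np.array([config.goslim_categories[c] for c in cats], dtype=float)
    cat_p = cat_p / cat_p.sum()

    n_par = config.n_parasite_transcripts
    ancestors = [_random_seq(rng, int(rng.integers(lo, hi + 1))) for _ in range(n_par)]

    # which parasite transcripts appear in each companion database
    in_parasite_ref = rng.random(n_par) < config.parasite_reference_coverage
    in_annotation = rng.random(n_par) < config.annotation_coverage

    parasite_reference = {}
    annotation_db = {}
    anno_rows = []
    truth_rows = []
    parasite_assembly = {}

    og_regions = rng.choice(len(regions), size=n_par, p=region_p)
    goslims = rng.choice(len(cats), size=n_par, p=cat_p)
    expr = rng.gamma(
        1.0 / config.expression.dispersion,
        config.expression.mean * config.expression.dispersion,
        size=n_par,
    )

    for i, anc in enumerate(ancestors):
        uid = f"unigene_{i:05d}"
        og = f"OG{i:05d}"
        parasite_assembly[uid] = anc
        if in_parasite_ref[i]:
            parasite_reference[f"TvRef_{i:05d}"] = mutate(
                anc, config.divergence_within_parasite, rng, config.indel_rate
            )
        if in_annotation[i]:
            sid = f"Anno_{i:05d}"
            annotation_db[sid] = mutate(
                anc, config.divergence_annotation, rng, config.indel_rate
            )
            anno_rows.append(
                {
                    "subject_id": sid,
                    "kingdom": "plant",
                    "orthogroup": og,
                    "goslim": cats[goslims[i]],
                }
            )
        if in_parasite_ref[i]:
            true_cat = "parasite"
        elif in_annotation[i]:
            true_cat = "other_plant"
        else:
            true_cat = "no_hit"
        truth_rows.append(
            {
                "unigene_id": uid,
                "origin": "parasite",
                "true_category": true_cat,
                "orthogroup": og,
                "region": regions[og_regions[i]],
                "goslim": cats[goslims[i]],
                "true_expression": expr[i],
            }
        )

    # host references: homologs of a subset of the parasite ancestors plus
    # independent mutation streams per host species
    host_a, host_b = {}, {}
    host_idx = rng.permutation(n_par)[: config.n_host_transcripts]
    for j, i in enumerate(sorted(host_idx)):
        host_a[f"HostA_{j:05d}"] = mutate(
            ancestors[i], config.divergence_parasite_host, rng, config.indel_rate
        )
        host_b[f"HostB_{j:05d}"] = mutate(
            ancestors[i], config.divergence_parasite_host, rng, config.indel_rate
        )

    control = {
        f"Ctl_{i:05d}": mutate(anc, config.divergence_control, rng, config.indel_rate)
        for i, anc in enumerate(ancestors)
    }

    # planted host contaminant unigenes: near-exact copies of host transcripts
    host_a_ids = sorted(host_a)
    for j in range(config.n_contaminant_unigenes):
        src = host_a_ids[int(rng.integers(0, len(host_a_ids)))]
        uid = f"unigene_{n_par + j:05d}"
        parasite_assembly[uid] = mutate(host_a[src], 0.003, rng)
        truth_rows.append(
            {
                "unigene_id": uid,
                "origin": "host_a",
                "true_category": "host",
                "orthogroup": "",
                "region": "",
                "goslim": "",
                "true_expression": 0.0,
            }
        )

    # non-plant unigenes with labeled sources in the annotation database
    base = n_par + config.n_contaminant_unigenes
    for j in range(config.n_nonplant_unigenes):
        seq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        uid = f"unigene_{base + j:05d}"
        sid = f"Anno_NP_{j:05d}"
        parasite_assembly[uid] = seq
        annotation_db[sid] = mutate(seq, 0.02, rng)
        anno_rows.append(
            {"subject_id": sid, "kingdom": "non_plant", "orthogroup": "", "goslim": ""}
        )
        truth_rows.append(
            {
                "unigene_id": uid,
                "origin": "non_plant",
                "true_category": "non_plant",
                "orthogroup": "",
                "region": "",
                "goslim": "",
                "true_expression": 0.0,
            }
        )

    # unigenes with no counterpart anywhere
    base += config.n_nonplant_unigenes
    for j in range(config.n_unknown_unigenes):
        uid = f"unigene_{base + j:05d}"
        parasite_assembly[uid] = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        truth_rows.append(
            {
                "unigene_id": uid,
                "origin": "unknown",
                "true_category": "no_hit",
                "orthogroup": "",
                "region": "",
                "goslim": "",
                "true_expression": 0.0,
            }
        )

    return ReferenceSets(
        parasite_assembly=parasite_assembly,
        parasite_reference=parasite_reference,
        host_a=host_a,
        host_b=host_b,
        control=control,
        annotation_db=annotation_db,
        annotation_labels=pd.DataFrame(
            anno_rows, columns=["subject_id", "kingdom", "orthogroup", "goslim"]
        ),
        truth=pd.DataFrame(truth_rows),
    )


def _phred_profile(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-position base qualities: high at the 5' end, sagging at the 3' end."""
    pos = np.arange(config.read_length)
    base = 38.0 - 8.0 * pos / max(config.read_length - 1, 1)
    q = base + rng.normal(0, 1.5, size=config.read_length)
    return np.clip(np.rint(q), 2, 40).astype(int)


def _sequence_read(seq: str, rng: np.random.Generator, config: SimulationConfig):
    quals = _phred_profile(config, rng)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    err = rng.random(arr.size) < config.base_error_rate
    if config.low_quality_tail_prob > 0 and rng.random() < config.low_quality_tail_prob:
        # tails long enough that some reads fail the half-length survival rule
        tail = int(rng.integers(5, max(6, 3 * config.read_length // 4)))
        quals[-tail:] = rng.integers(2, 15, size=tail)
        err[-tail:] |= rng.random(tail) < 0.2
    if err.any():
        shifts = rng.integers(1, 4, size=int(err.sum()))
        idx = np.searchsorted(BASES, arr[err])
        arr[err] = BASES[(idx + shifts) % 4]
    return arr.tobytes().decode("ascii"), quals.tolist()


def simulate_mixed_library(
    config: SimulationConfig, refs: ReferenceSets
) -> tuple[list, pd.DataFrame]:
    """Paired-end reads from parasite transcripts contaminated by host A.

    Returns ``(pairs, origins)`` where each pair is
    ``(read_id, seq1, qual1, seq2, qual2)`` and origins records the true
    source of every pair.  The expected fraction of host-origin pairs is the
    configured contamination fraction ``f``.
    """
    config.validate()
    rng = config.rng(1)
    truth = refs.truth
    par_ids = truth.loc[truth.origin == "parasite", "unigene_id"].tolist()
    par_expr = truth.loc[truth.origin == "parasite", "true_expression"].to_numpy()
    par_seqs = [refs.parasite_assembly[u] for u in par_ids]
    host_ids = sorted(refs.host_a)
    host_seqs = [refs.host_a[h] for h in host_ids]
    host_expr = rng.gamma(
        1.0 / config.expression.dispersion,
        config.expression.mean * config.expression.dispersion,
        size=len(host_ids),
    )

    rl = config.read_length
    min_len = min(min(map(len, par_seqs)), min(map(len, host_seqs)))
    if rl > min_len:
        raise ValueError(
            f"read_length {rl} exceeds shortest transcript length {min_len}"
        )

    def weights(expr_arr, seqs):
        w = expr_arr * np.array([len(s) for s in seqs], dtype=float)
        return w / w.sum()

    w_par = weights(par_expr, par_seqs)
    w_host = weights(host_expr, host_seqs)

    pairs = []
    origin_rows = []
    is_host = rng.random(config.n_read_pairs) < config.contamination_fraction
    for i in range(config.n_read_pairs):
        if is_host[i]:
            t = int(rng.choice(len(host_ids), p=w_host))
            src_id, seq, origin = host_ids[t], host_seqs[t], "host_a"
        else:
            t = int(rng.choice(len(par_ids), p=w_par))
            src_id, seq, origin = par_ids[t], par_seqs[t], "parasite"
        L = len(seq)
        insert = int(
            np.clip(rng.normal(config.insert_size_mean, config.insert_size_sd), rl, L)
        )
        start = int(rng.integers(0, L - insert + 1))
        frag = seq[start : start + insert]
        m1, q1 = _sequence_read(frag[:rl], rng, config)
        m2, q2 = _sequence_read(revcomp(frag[-rl:]), rng, config)
        rid = f"pair_{i:06d}"
        pairs.append((rid, m1, q1, m2, q2))
        origin_rows.append({"read_id": rid, "origin": origin, "source": src_id})
    return pairs, pd.DataFrame(origin_rows, columns=["read_id", "origin", "source"])


def simulate_orthogroup_sets(config: SimulationConfig):
    """Orthogroup id sets for (interface A, interface B, above-ground).

    Each orthogroup is planted in one of the seven Venn regions according to
    ``region_proportions``; membership in the three transcriptomes follows.
    Returns ``(set_a, set_b, set_ref, region_truth)``.
    """
    rng = config.rng(3)
    regions = list(config.region_proportions)
    p = np.array([config.region_proportions[r] for r in regions], dtype=float)
    p = p / p.sum()
    assignment = rng.choice(len(regions), size=config.n_orthogroups, p=p)
    in_a = {"shared_all", "interface_shared", "A_interface_unique", "A_above_shared"}
    in_b = {"shared_all", "interface_shared", "B_interface_unique", "B_above_shared"}
    in_ref = {"shared_all", "A_above_shared", "B_above_shared", "above_unique"}
    set_a, set_b, set_ref = set(), set(), set()
    region_truth = {}
    for i, ridx in enumerate(assignment):
        og = f"OG{i:05d}"
        region = regions[ridx]
        region_truth[og] = region
        if region in in_a:
            set_a.add(og)
        if region in in_b:
            set_b.add(og)
        if region in in_ref:
            set_ref.add(og)
    return set_a, set_b, set_ref, region_truth


def simulate_goslim_table(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """GO Slim category x Venn region contingency table with planted enrichment.

    Per orthogroup, a region is drawn from ``region_proportions`` and a GO
    Slim category from the base category distribution tilted by the planted
    per-region log-odds.  Returns the count table (categories as rows,
    regions as columns) and the planted (region, category) cells.
    """
    rng = config.rng(4)
    regions = list(config.region_proportions)
    p_region = np.array([config.region_proportions[r] for r in regions], dtype=float)
    p_region = p_region / p_region.sum()
    cats = list(config.goslim_categories)
    base = np.array([config.goslim_categories[c] for c in cats], dtype=float)
    base = base / base.sum()

    table = pd.DataFrame(0, index=cats, columns=regions, dtype=int)
    reg_draw = rng.choice(len(regions), size=config.n_orthogroups, p=p_region)
    for ridx in reg_draw:
        region = regions[ridx]
        odds = base.copy()
        for cat, lo in config.enrichment_log_odds.get(region, {}).items():
            odds[cats.index(cat)] *= np.exp(lo)
        odds = odds / odds.sum()
        cidx = int(rng.choice(len(cats), p=odds))
        table.loc[cats[cidx], region] += 1
    planted = {
        (region, cat): lo
        for region, d in config.enrichment_log_odds.items()
        for cat, lo in d.items()
    }
    return table, planted


def simulate_qpcr(config: SimulationConfig) -> pd.DataFrame:
    """Ct replicate table with known true fold changes.

    Columns: sample, condition, gene, bio_rep, tech_rep, ct.  Each sample
    carries a loading shift common to all its genes (it cancels in delta-Ct),
    plus independent technical noise per well.  With zero noise the
    2^-ddCt estimate equals the configured fold exactly.
    """
    config.validate()
    rng = config.rng(2)
    q = config.qpcr
    rows = []
    for condition in ("control", "treatment"):
        for b in range(1, q.n_bio_replicates + 1):
            sample = f"{condition}_{b}"
            shift = rng.normal(0, q.loading_sd) if q.loading_sd > 0 else 0.0
            gene_ct = {"reference": q.reference_ct + shift}
            for gene, fold in q.true_fold.items():
                delta = q.control_delta_ct
                if condition == "treatment":
                    delta = delta - float(np.log2(fold))
                gene_ct[gene] = q.reference_ct + shift + delta
            for gene, ct0 in gene_ct.items():
                for t in range(1, q.n_tech_replicates + 1):
                    noise = rng.normal(0, q.ct_noise_sd) if q.ct_noise_sd > 0 else 0.0
                    rows.append(
                        {
                            "sample": sample,
                            "condition": condition,
                            "gene": gene,
                            "bio_rep": b,
                            "tech_rep": t,
                            "ct": ct0 + noise,
                        }
                    )
    return pd.DataFrame(rows, columns=["sample", "condition", "gene", "bio_rep", "tech_rep", "ct"])
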