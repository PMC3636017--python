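"""Deduplication, translatability, the classification cascade, and N50."""

import numpy as np
import pandas as pd
import pytest

from interphyte.classify import (
    ambiguous_band,
    assembly_stats,
    cascade_accounting,
    classify_cascade,
    deduplicate,
    longest_orf_length,
    n50,
    translatability_filter,
)
from interphyte.similarity import MappingPolicy, revcomp
from interphyte.simulate import simulate_reference_sets

from conftest import small_config
from oracles import brute_containment


class TestDeduplicate:
    def test_exact_duplicate_removed(self):
        kept, removed = deduplicate({"a": "ACGTACGTAA", "b": "ACGTACGTAA"})
        assert list(kept) == ["a"]
        assert removed == ["b"]

    def test_contained_substring_removed(self):
        kept, removed = deduplicate({"long": "ACGTACGT", "short": "GTAC"})
        assert "long" in kept and removed == ["short"]

    def test_reverse_complement_containment_removed(self):
        kept, removed = deduplicate({"long": "AACCGGTTACGT", "rc": revcomp("CCGGTTAC")})
        assert removed == ["rc"]

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 12))
            seqs = {}
            for i in range(n):
                L = int(rng.integers(8, 30))
                seqs[f"u{i}"] = "".join(rng.choice(list("ACGT"), size=L))
                if rng.random() < 0.4 and seqs:
                    donor = seqs[list(seqs)[int(rng.integers(0, len(seqs)))]]
                    a = int(rng.integers(0, max(len(donor) - 4, 1)))
                    seqs[f"u{i}"] = donor[a : a + int(rng.integers(4, len(donor) - a + 1))]
            kept, removed = deduplicate(seqs)
            assert set(removed) == brute_containment(seqs)
            assert set(kept) | set(removed) == set(seqs)


class TestTranslatability:
    def test_stop_free_frame_always_kept(self):
        seq = "ATGGCT" * 30  # Met-Ala repeats, no stops
        assert translatability_filter(seq, 1.0)

    def test_stop_riddled_sequence_dropped(self, rng):
        # a stop codon roughly every 8 codons in every frame
        core = []
        for _ in range(40):
            core.append("".join(rng.choice(list("ACGT"), size=21)) + "TAA")
        seq = "".join(core)
        assert longest_orf_length(seq) < 0.5 * len(seq)
        assert not translatability_filter(seq, 0.5)

    def test_too_short_for_a_codon_dropped(self):
        assert not translatability_filter("AC", 0.1)


class TestCascade:
    def test_host_stage_wins_over_parasite(self, rng):
        """A unigene identical to a host reference is host even when the
        parasite database contains the same sequence."""
        seq = "".join(rng.choice(list("ACGT"), size=400))
        classified, _ = classify_cascade(
            {"u1": seq},
            host_db={"h1": seq},
            parasite_db={"p1": seq},
            annotation_db={},
            annotation_labels=pd.DataFrame(columns=["subject_id", "kingdom"]),
        )
        assert classified[0].category == "host"
        assert classified[0].stage_decided == "host_screen"

    def test_missing_taxon_label_is_config_error(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=200))
        with pytest.raises(ValueError, match="Anno_x"):
            classify_cascade(
                {"u1": seq},
                host_db={},
                parasite_db={},
                annotation_db={"Anno_x": seq},
                annotation_labels=pd.DataFrame(columns=["subject_id", "kingdom"]),
            )

    def test_synthetic_cascade_recovers_ground_truth(self, config, refs):
        """Category-level precision/recall vs ground truth with a wide
        divergence gap."""
        classified, acc = classify_cascade(
            refs.parasite_assembly,
            refs.host_a,
            refs.parasite_reference,
            refs.annotation_db,
            refs.annotation_labels,
            tau_host=95.0,
            tau_parasite=95.0,
        )
        truth = refs.truth.set_index("unigene_id")["true_category"]
        pred = pd.Series({c.unigene_id: c.category for c in classified})
        acc_rate = (pred.loc[truth.index] == truth).mean()
        assert acc_rate >= 0.95
        # conservation: categories sum to input
        table = acc.set_index("stage")["count"]
        assert (
            table["host_unigenes"] + table["non_plant_unigenes"]
            + table["putative_parasite_unigenes"] == table["unigenes_total"]
        )
        assert (
            table["parasite_hits"] + table["other_plant_hits"] + table["no_hits"]
            == table["putative_parasite_unigenes"]
        )

    def test_raising_tau_host_never_increases_host_count(self, config, refs):
        sub = dict(list(refs.parasite_assembly.items())[:40])
        counts = []
        for tau in (90.0, 96.0, 99.5):
            classified, _ = classify_cascade(
                sub, refs.host_a, refs.parasite_reference,
                refs.annotation_db, refs.annotation_labels,
                tau_host=tau,
            )
            counts.append(sum(c.category == "host" for c in classified))
        assert counts[0] >= counts[1] >= counts[2]

    def test_ambiguous_band_lists_dual_threshold_unigenes(self, rng):
        shared = "".join(rng.choice(list("ACGT"), size=300))
        only_host = "".join(rng.choice(list("ACGT"), size=300))
        band = ambiguous_band(
            {"dual": shared, "hostish": only_host},
            host_db={"h": shared, "h2": only_host},
            parasite_db={"p": shared},
        )
        assert band == ["dual"]


class TestAccountingFixture:
    def test_interface_assembly_accounting_z_mays(self):
        """28,126 unigenes with 4,967 host and 127 non-plant leave a putative
        parasite pool of 23,032, split 17,887 / 2,975 / 2,170."""
        acc = cascade_accounting(
            total=28_126, host=4_967, non_plant=127, parasite=17_887, other_plant=2_975
        ).set_index("stage")["count"]
        assert acc["putative_parasite_unigenes"] == 23_032
        assert acc["no_hits"] == 2_170

    def test_interface_assembly_accounting_m_truncatula(self):
        acc = cascade_accounting(
            total=26_709, host=7_785, non_plant=329, parasite=14_352, other_plant=2_086
        ).set_index("stage")["count"]
        assert acc["putative_parasite_unigenes"] == 18_595
        assert acc["no_hits"] == 2_157

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            cascade_accounting(total=10, host=5, non_plant=5, parasite=3, other_plant=0)


class TestAssemblyStats:
    def test_n50_hand_calculation(self):
        assert n50([400, 300, 200, 100]) == 300

    def test_single_and_uniform_sets(self):
        assert n50([777]) == 777
        assert n50([250, 250, 250]) == 250

    def test_stats_invariants(self, refs):
        s = assembly_stats(refs.parasite_assembly)
        assert s.min_length <= s.n50 <= s.max_length
        assert s.total_length == sum(len(x) for x in refs.parasite_assembly.values())

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            assembly_stats({})
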