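"""Consensus KO mapping, pathway sets, GSVA-style scores, significance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from peptaxa.pepfunc import (
    build_peptide_ko_db,
    consensus_ko,
    enrichment_significance,
    gsva_scores,
    pathway_peptide_sets,
)
from peptaxa.peptide_io import PeptideObservation


def ob(seq, group):
    return PeptideObservation(seq, tuple(group), {"s1": 1.0})


class TestConsensusKO:
    @pytest.mark.parametrize(
        "kos,expected",
        [
            (["K00001", "K00001"], "K00001"),
            (["K00001", "K00002"], None),
            (["K00001", None], None),
            ([None, None], None),
            (["K00003"], "K00003"),
        ],
    )
    def test_rule(self, kos, expected):
        table = {f"P{i}": ko for i, ko in enumerate(kos)}
        assert consensus_ko(ob("AAAK", list(table)), table) == expected

    def test_invariant_to_order_and_duplication(self):
        table = {"P1": "K00001", "P2": "K00001"}
        a = consensus_ko(ob("AAAK", ["P1", "P2"]), table)
        b = consensus_ko(ob("AAAK", ["P2", "P1", "P1", "P2"]), table)
        assert a == b == "K00001"

    def test_dedup_indirection(self):
        table = {"REP": "K00009"}
        assert (
            consensus_ko(ob("AAAK", ["OLD"]), table, dedup_map={"OLD": "REP"})
            == "K00009"
        )

    def test_exhaustive_patterns_match_strict_consensus_truth(self):
        # every KO-group pattern of size ≤4 from a 3-KO alphabet plus absent
        alphabet = ["K00001", "K00002", "K00003", None]
        for size in (1, 2, 3, 4):
            for pattern in itertools.product(alphabet, repeat=size):
                table = {f"P{i}": ko for i, ko in enumerate(pattern)}
                distinct = set(pattern)
                expected = (
                    pattern[0]
                    if len(distinct) == 1 and pattern[0] is not None
                    else None
                )
                got = consensus_ko(ob("AAAK", list(table)), table)
                assert got == expected, pattern


class TestPeptideKODb:
    def test_only_consensus_mappable_rows(self):
        table = {"P1": "K00001", "P2": "K00001", "P3": "K00002", "P4": None}
        obs = [
            ob("AAAK", ["P1", "P2"]),  # consensus
            ob("CCCK", ["P1", "P3"]),  # disagreement
            ob("DDDK", ["P4"]),  # absent
            ob("EEEK", ["P3"]),  # consensus
            ob("FFFK", ["P1", "P4"]),  # partial
        ]
        ko_map, df = build_peptide_ko_db(obs, table)
        assert ko_map == {"AAAK": "K00001", "EEEK": "K00002"}
        assert list(df.columns) == ["peptide", "ko"]
        assert len(df) == 2

    def test_no_mappable_peptides_gives_empty_table_with_header(self, tmp_path):
        out = tmp_path / "pep2ko.tsv"
        _, df = build_peptide_ko_db([ob("AAAK", ["P9"])], {"P9": None}, out_path=out)
        assert df.empty
        assert out.read_text().splitlines()[0] == "peptide\tko"

    def test_matches_per_peptide_rule_on_synthetic_fixture(self, dedup, peptide_data):
        _, truth = peptide_data
        microbial = truth[truth["origin"] == "microbial"]
        obs = [ob(r.peptide, r.proteins.split(";")) for r in microbial.itertuples()]
        ko_map, _ = build_peptide_ko_db(obs, dedup.ko_map(), dedup.dedup_map)
        for row in microbial.itertuples():
            assert ko_map.get(row.peptide, "") == row.true_ko


class TestPathwaySets:
    TABLE = pd.DataFrame(
        {
            "ko": ["K00001", "K00001", "K00002"],
            "pathway_id": ["pw1", "pw2", "pw1"],
        }
    )

    def test_ko_in_two_pathways_joins_both(self):
        ko_map = {f"pep{i}": "K00001" for i in range(5)}
        sets = pathway_peptide_sets(ko_map, self.TABLE, min_size=5)
        assert sets == {"pw1": set(ko_map), "pw2": set(ko_map)}

    def test_min_size_drops_small_pathways(self):
        ko_map = {f"pep{i}": "K00002" for i in range(4)}
        assert pathway_peptide_sets(ko_map, self.TABLE, min_size=5) == {}

    def test_sizes_equal_relational_join(self, rng):
        kos = [f"K{i + 1:05d}" for i in range(10)]
        ko_map = {f"pep{i}": kos[int(rng.integers(10))] for i in range(200)}
        rows = [
            {"ko": k, "pathway_id": f"pw{j}"}
            for j in range(6)
            for k in rng.choice(kos, size=4, replace=False)
        ]
        table = pd.DataFrame(rows)
        sets = pathway_peptide_sets(ko_map, table, min_size=1)
        join = (
            pd.DataFrame({"peptide": list(ko_map), "ko": list(ko_map.values())})
            .merge(table, on="ko")
            .groupby("pathway_id")["peptide"]
            .nunique()
        )
        assert {p: len(s) for p, s in sets.items()} == join.to_dict()


def oracle_gsva(matrix: pd.DataFrame, sets: dict, tau=1.0, method="maxdev"):
    """Independently coded brute-force walk (plain Python loops)."""
    out = {}
    peptides = list(matrix.index)
    p = len(peptides)
    for pathway, members in sets.items():
        out[pathway] = {}
        for sample in matrix.columns:
            x = np.log2(matrix[sample].to_numpy(dtype=float) + 1.0)
            ranks = stats.rankdata(x)
            weights = {
                pep: abs(r - (p + 1) / 2) ** tau for pep, r in zip(peptides, ranks)
            }
            ordered = sorted(peptides, key=lambda q: (-x[peptides.index(q)], q))
            in_set = [q in members for q in ordered]
            m = sum(in_set)
            w_total = sum(weights[q] for q, isin in zip(ordered, in_set) if isin)
            dev, best = 0.0, 0.0
            cum_in = cum_out = 0.0
            for q, isin in zip(ordered, in_set):
                if isin:
                    cum_in += weights[q] / w_total if w_total else 0.0
                else:
                    cum_out += 1.0 / (p - m)
                d = cum_in - cum_out
                if abs(d) > abs(dev):
                    dev = d
                best = max(best, d)
            if method == "maxdev":
                out[pathway][sample] = dev
            else:
                out[pathway][sample] = best  # not used in tests
    return out


@pytest.fixture()
def random_matrix(rng):
    peptides = [f"PEP{i:03d}" for i in range(20)]
    data = rng.lognormal(16, 1.5, size=(20, 4))
    return pd.DataFrame(data, index=peptides, columns=["s1", "s2", "s3", "s4"])


class TestGSVAScores:
    def test_matches_bruteforce_oracle(self, random_matrix, rng):
        peptides = list(random_matrix.index)
        sets = {
            f"pw{j}": set(rng.choice(peptides, size=int(rng.integers(3, 10)), replace=False))
            for j in range(5)
        }
        scores = gsva_scores(random_matrix, sets)
        expected = oracle_gsva(random_matrix, sets)
        for pathway in sets:
            for sample in random_matrix.columns:
                assert scores.loc[pathway, sample] == pytest.approx(
                    expected[pathway][sample], abs=1e-9
                )

    def test_invariant_under_monotone_transforms(self, random_matrix, rng):
        peptides = list(random_matrix.index)
        sets = {"pw": set(rng.choice(peptides, size=7, replace=False))}
        base = gsva_scores(random_matrix, sets)
        transformed = random_matrix.copy()
        transformed["s1"] = np.exp(transformed["s1"] / transformed["s1"].max() * 4)
        transformed["s2"] = transformed["s2"] ** 3
        transformed["s3"] = transformed["s3"].rank()
        alt = gsva_scores(transformed, sets)
        pd.testing.assert_frame_equal(base, alt)

    def test_top_ranked_set_scores_positive_and_maximal(self, rng):
        peptides = [f"PEP{i:03d}" for i in range(20)]
        data = rng.lognormal(10, 0.2, size=(20, 3))
        matrix = pd.DataFrame(data, index=peptides, columns=["s1", "s2", "s3"])
        top = set(peptides[:5])
        matrix.loc[sorted(top), "s1"] *= 1e5  # uniformly top-ranked in s1
        sets = {"top": top}
        sets.update(
            {
                f"null{j}": set(rng.choice(peptides[5:], size=5, replace=False))
                for j in range(4)
            }
        )
        scores = gsva_scores(matrix, sets)
        assert scores.loc["top", "s1"] > 0
        assert scores.loc["top", "s1"] == scores["s1"].max()

    def test_degenerate_all_peptide_set_scores_small(self, random_matrix):
        scores = gsva_scores(random_matrix, {"all": set(random_matrix.index)})
        assert (scores.abs() < 0.3).all().all()

    def test_scores_bounded(self, random_matrix, rng):
        peptides = list(random_matrix.index)
        sets = {
            f"pw{j}": set(rng.choice(peptides, size=4, replace=False)) for j in range(6)
        }
        for method in ("maxdev", "diff"):
            scores = gsva_scores(random_matrix, sets, method=method)
            assert (scores.abs() <= 1.0).all().all()

    def test_disjoint_pathway_skipped_with_warning(self, random_matrix):
        with pytest.warns(UserWarning, match="skipped"):
            scores = gsva_scores(
                random_matrix,
                {"ghost": {"NOPE"}, "ok": set(random_matrix.index[:5])},
            )
        assert list(scores.index) == ["ok"]

    def test_fewer_than_three_samples_rejected(self, random_matrix):
        with pytest.raises(ValueError):
            gsva_scores(random_matrix.iloc[:, :2], {"pw": {"PEP000"}})


class TestEnrichmentSignificance:
    GROUPS = {f"s{i + 1}": ("crewA" if i < 3 else "crewB") for i in range(6)}

    def test_identical_scores_are_nonsignificant(self):
        scores = pd.DataFrame(
            np.ones((4, 6)), index=[f"pw{j}" for j in range(4)], columns=self.GROUPS
        )
        res = enrichment_significance(scores, self.GROUPS, alpha=0.05)
        assert (res["p_adjusted"] == 1.0).all()
        assert not res["significant"].any()

    def test_injected_shift_has_smallest_adjusted_p(self, rng):
        scores = pd.DataFrame(
            rng.normal(0, 0.1, size=(20, 6)),
            index=[f"pw{j}" for j in range(20)],
            columns=self.GROUPS,
        )
        scores.loc["pw7", ["s4", "s5", "s6"]] += 2.0
        res = enrichment_significance(scores, self.GROUPS, alpha=0.05)
        assert res["p_adjusted"].idxmin() == "pw7"

    def test_bh_preserves_raw_p_ordering(self, rng):
        scores = pd.DataFrame(
            rng.normal(size=(15, 6)),
            index=[f"pw{j}" for j in range(15)],
            columns=self.GROUPS,
        )
        res = enrichment_significance(scores, self.GROUPS)
        by_raw = res.sort_values("p_value")
        assert by_raw["p_adjusted"].is_monotonic_increasing

    def test_degenerate_groups_rejected(self, rng):
        scores = pd.DataFrame(
            rng.normal(size=(3, 6)),
            index=["a", "b", "c"],
            columns=self.GROUPS,
        )
        with pytest.raises(ValueError):
            enrichment_significance(scores, {s: "same" for s in self.GROUPS})
        lonely = dict(self.GROUPS)
        lonely["s6"] = "crewC"
        with pytest.raises(ValueError):
            enrichment_significance(scores, lonely)
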