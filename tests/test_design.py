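import numpy as np
import pytest

from degenmix.core import DegenerateSequence, DesignRules, count_degenerate_positions
from degenmix.design import (
    InfeasibleGroup,
    PrimerVariant,
    coverage_of,
    minimal_variant_for_group,
    partition_targets,
    relax_variant,
    relaxed_mix,
    spacing_score,
    variant_from_oligo,
)
from degenmix.fixtures import _FW_SKELETON

from bruteforce import CODES, bf_optimal_partition_size, expansions

FLIP = {"A": "T", "T": "A"}
VARIABLE = [1, 3, 5, 7, 9, 13, 17, 20]  # A/T positions of the skeleton


def _window(flips):
    """A QC-compliant 22-mer: the skeleton with A<->T flips at `flips`."""
    s = list(_FW_SKELETON)
    for p in flips:
        s[p] = FLIP[s[p]]
    return "".join(s)


def _random_panel(rng, n):
    return {
        f"t{i + 1}": _window([p for p in VARIABLE if rng.random() < 0.4])
        for i in range(n)
    }


class TestMinimalVariant:
    def test_identical_rows_give_zero_degeneracy(self, rules):
        rows = {"a": _window([]), "b": _window([])}
        v = minimal_variant_for_group(rows, rules)
        assert v.n_degenerate == 0
        assert v.seq.bases == _FW_SKELETON
        assert v.covered_ids == {"a", "b"}

    def test_two_nonadjacent_differences_are_feasible(self, rules):
        rows = {"a": _window([]), "b": _window([3, 9])}
        v = minimal_variant_for_group(rows, rules)
        assert v.n_degenerate == 2

    def test_five_differences_violate_the_cap(self, rules):
        rows = {"a": _window([]), "b": _window([1, 5, 9, 13, 17])}
        with pytest.raises(InfeasibleGroup, match="no more than 4"):
            minimal_variant_for_group(rows, rules)

    def test_adjacent_degeneracies_are_rejected(self, rules):
        a = _window([])
        b = a[:9] + ("T" if a[9] == "A" else "A") + a[10:]
        b = b[:10] + ("C" if a[10] != "C" else "T") + b[11:]
        with pytest.raises(InfeasibleGroup, match="consecutive"):
            minimal_variant_for_group({"a": a, "b": b}, rules)

    def test_empty_group_is_an_error(self, rules):
        with pytest.raises(Exception):
            minimal_variant_for_group({}, rules)


class TestPartition:
    def test_identical_targets_need_one_variant(self, rules):
        rows = {f"t{i}": _window([]) for i in range(4)}
        mix = partition_targets(rows, rules)
        assert len(mix.variants) == 1
        assert mix.variants[0].n_degenerate == 0
        assert mix.union_coverage == set(rows)

    def test_two_clades_differing_at_six_positions(self, rules):
        """Two clades 6 variable positions apart force exactly 2 groups."""
        clade1 = [_window([]), _window([1]), _window([5])]
        clade2 = [_window([1, 3, 7, 9, 13, 17]), _window([3, 7, 9, 13, 17])]
        rows = {f"a{i}": s for i, s in enumerate(clade1)}
        rows.update({f"b{i}": s for i, s in enumerate(clade2)})
        mix = partition_targets(rows, rules)
        assert len(mix.variants) == bf_optimal_partition_size(rows) == 2
        assert mix.union_coverage == set(rows)

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_partition_matches_exhaustive_search(self, rules, seed):
        rng = np.random.default_rng(seed)
        rows = _random_panel(rng, int(rng.integers(3, 8)))
        mix = partition_targets(rows, rules)
        assert len(mix.variants) == bf_optimal_partition_size(rows)
        assert mix.union_coverage == set(rows)

    @pytest.mark.parametrize("seed", range(4))
    def test_greedy_covers_everything_with_compliant_variants(self, rules, seed):
        rng = np.random.default_rng(100 + seed)
        rows = _random_panel(rng, 20)
        mix = partition_targets(rows, rules, exact_limit=0)  # force greedy
        assert mix.union_coverage == set(rows)
        for v in mix.variants:
            assert_variant_compliant(v, rows)

    def test_groups_named_by_decreasing_coverage(self, panel, rules):
        mix = partition_targets(panel.region_windows(panel.fw_region), rules)
        sizes = [len(v.covered_ids) for v in mix.variants]
        assert sizes == sorted(sizes, reverse=True)
        assert [v.name for v in mix.variants] == [
            f"G{i + 1}" for i in range(len(mix.variants))
        ]

    def test_panel_greedy_designs_at_most_seven_variants(self, panel, rules):
        mix = partition_targets(panel.region_windows(panel.fw_region), rules)
        assert len(mix.variants) <= 7
        assert len(mix.union_coverage) == 24


def assert_variant_compliant(v: PrimerVariant, targets: dict[str, str]):
    """Independent re-check of every degeneracy/thermo rule on a variant."""
    s = v.seq.bases
    assert 17 <= len(s) <= 22
    deg = [i for i, c in enumerate(s) if len(CODES[c]) > 1]
    assert len(deg) <= 4
    assert all(b - a > 1 for a, b in zip(deg, deg[1:]))
    gcs = [sum(1 for x in e if x in "GC") for e in expansions(s)]
    for gc in (min(gcs), max(gcs)):
        tm = 64.9 + 41.0 * (gc - 16.4) / len(s)
        assert 50 <= tm <= 65
    assert max(gcs) / len(s) < 0.50
    # declared coverage is exact zero-mismatch matching
    for rid in v.covered_ids:
        assert all(targets[rid][i] in CODES[s[i]] for i in range(len(s)))


class TestRelax:
    def test_relaxation_recovers_the_planted_wider_variant(self, panel, rules):
        wins = panel.region_windows(panel.fw_region)
        g1 = next(o for o in panel.mixes["Fw1_mixA"] if o.name == "Fw1_G1")
        g1n = next(o for o in panel.mixes["Fw1_mixB"] if o.name == "Fw1_G1n")
        v = variant_from_oligo(g1, wins, rules)
        r = relax_variant(v, wins, rules)
        assert r.name == "Fw1_G1n"
        assert r.seq.bases == g1n.bases
        assert r.covered_ids > v.covered_ids

    def test_relaxation_never_loses_coverage(self, rules):
        rng = np.random.default_rng(5)
        for _ in range(10):
            rows = _random_panel(rng, 10)
            mix = partition_targets(rows, rules)
            for v in mix.variants:
                if v.n_degenerate >= rules.max_degenerate:
                    continue
                r = relax_variant(v, rows, rules)
                assert r.covered_ids >= v.covered_ids

    def test_single_position_relaxation_found_by_enumeration(self, rules):
        """The chosen relaxation matches a brute force over positions x codes."""
        base = _window([])
        rows = {"a": base, "b": _window([1]), "c": _window([5])}
        # two extra targets differing from the group only at position 17
        rows["d"] = _window([17])
        rows["e"] = _window([17])
        v = minimal_variant_for_group({k: rows[k] for k in "abc"}, rules, panel=rows)
        r = relax_variant(v, rows, rules)
        # brute force: try every position and every wider code
        best_gain = 0
        for p in range(len(v.seq.bases)):
            for code, bases in CODES.items():
                if len(bases) <= len(CODES[v.seq.bases[p]]):
                    continue
                if set(CODES[v.seq.bases[p]]) - set(bases):
                    continue
                cand = v.seq.bases[:p] + code + v.seq.bases[p + 1 :]
                deg = [i for i, c in enumerate(cand) if len(CODES[c]) > 1]
                if len(deg) > 4 or any(y - x == 1 for x, y in zip(deg, deg[1:])):
                    continue
                cov = sum(
                    all(s[i] in CODES[cand[i]] for i in range(len(cand)))
                    for s in rows.values()
                )
                best_gain = max(best_gain, cov - len(v.covered_ids))
        assert len(r.covered_ids) - len(v.covered_ids) == best_gain == 2

    def test_full_coverage_variant_is_returned_unchanged(self, rules):
        rows = {"a": _window([]), "b": _window([9])}
        v = minimal_variant_for_group(rows, rules)
        assert relax_variant(v, rows, rules) is v

    def test_error_at_degeneracy_limit(self, rules):
        rows = {"a": _window([]), "b": _window([1, 5, 9, 13])}
        v = minimal_variant_for_group(rows, rules)
        assert v.n_degenerate == 4
        with pytest.raises(InfeasibleGroup, match="degeneracy limit"):
            relax_variant(v, rows, rules)

    def test_relaxed_mix_covers_at_least_as_much(self, panel, rules):
        wins = panel.region_windows(panel.fw_region)
        mix = partition_targets(wins, rules)
        relaxed = relaxed_mix(mix, wins, rules)
        assert relaxed.union_coverage >= mix.union_coverage


def test_spacing_score():
    def var(bases):
        s = DegenerateSequence(bases)
        return PrimerVariant(name="x", seq=s, covered_ids=frozenset(), qc=None)

    assert spacing_score(var("AAAYAAAAAYAAAAAYAAAA")) == 6
    assert spacing_score(var("AAAYAAAAAAAAAAAAAAAA")) == 20  # sentinel: length
    assert spacing_score(var("AAAYYAAAAAAAAAAAAAAA")) == 1
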