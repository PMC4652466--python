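import math

import numpy as np
import pytest

from otuclubs.clubs import (
    ClubPartition,
    club_stats,
    find_clubs,
    find_rival_clubs,
    write_club_summary_tsv,
    write_clubs_tsv,
    write_rivals_tsv,
)
from otuclubs.corrnet import build_network, correlation_with_significance
from otuclubs.mcl import MclParams
from otuclubs.preprocess import filter_otus, normalize_and_log
from otuclubs.synthgen import CommunitySpec, generate_community
from tests_helpers import crafted_correlation, make_network_from_masked


def block_masked(sizes, intra=0.6, inter=None):
    """Masked correlation matrix of positive blocks; ``inter[(a, b)] = r``
    fills the cross block."""
    n = sum(sizes)
    m = np.zeros((n, n))
    offs = np.cumsum([0] + list(sizes))
    for k, s in enumerate(sizes):
        blk = np.full((s, s), intra)
        np.fill_diagonal(blk, 0.0)
        m[offs[k] : offs[k] + s, offs[k] : offs[k] + s] = blk
    for (a, b), r in (inter or {}).items():
        m[offs[a] : offs[a + 1], offs[b] : offs[b + 1]] = r
        m[offs[b] : offs[b + 1], offs[a] : offs[a + 1]] = r
    return m


def pipeline_partition(spec):
    m, truth = generate_community(spec)
    f, _ = filter_otus(m)
    norm = normalize_and_log(f)
    c = correlation_with_significance(norm)
    net = build_network(c, norm.mean_log_abundance())
    return net, f, truth


class TestFindClubs:
    def test_small_clusters_unassigned(self):
        # clusters of sizes 5, 4, 2 -> 2 clubs and 2 unassigned nodes
        masked = block_masked([5, 4, 2])
        net, _ = make_network_from_masked(masked)
        part = find_clubs(net)
        assert [len(c.members) for c in part.clubs] == [5, 4]
        assert len(part.unassigned) == 2

    def test_planted_blocks_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        spec = CommunitySpec(
            seed=11, clubs=((8, 0.6), (8, 0.6), (8, 0.6)), n_background=10
        )
        net, f, truth = pipeline_partition(spec)
        part = find_clubs(net)
        club_of = part.club_of()
        pred = [club_of[o] for o in f.otu_ids]
        true = truth.labels(f.otu_ids)
        planted = true >= 0
        ari = adjusted_rand_score(true[planted], np.array(pred)[planted])
        assert ari == pytest.approx(1.0)

    def test_empty_edge_set(self):
        net, _ = make_network_from_masked(np.zeros((5, 5)))
        with pytest.warns(UserWarning, match="no edges"):
            part = find_clubs(net)
        assert part.clubs == []
        assert len(part.unassigned) == 5

    def test_leaders_belong_to_their_clubs(self):
        masked = block_masked([6, 4])
        net, _ = make_network_from_masked(masked)
        part = find_clubs(net)
        for c in part.clubs:
            assert c.leader in c.members

    def test_colors_by_decreasing_size(self):
        masked = block_masked([4, 7, 5])
        net, _ = make_network_from_masked(masked)
        part = find_clubs(net)
        sizes = [len(c.members) for c in part.clubs]
        assert sizes == sorted(sizes, reverse=True)
        assert [c.color_index for c in part.clubs] == list(range(len(sizes)))

    def test_partition_is_exhaustive_and_disjoint(self):
        masked = block_masked([5, 3, 2])
        net, _ = make_network_from_masked(masked)
        part = find_clubs(net)
        nodes = part.all_nodes()
        assert sorted(nodes) == sorted(net.nodes)
        assert len(nodes) == len(set(nodes))


class TestClubStats:
    def make(self, masked, clubs):
        net, _ = make_network_from_masked(masked)
        partition = ClubPartition(clubs, [n for n in net.nodes
                                          if all(n not in c.members for c in clubs)])
        return net, partition

    def test_uniform_intra(self):
        from otuclubs.clubs import Club

        masked = block_masked([3], intra=0.5)
        net, part = self.make(masked, [Club(["otu0", "otu1", "otu2"], "otu0", 0)])
        stats = club_stats(net, part)
        mean, sd, n = stats.intra[0]
        assert mean == pytest.approx(0.5)
        assert sd == pytest.approx(0.0)
        assert n == 3

    def test_uniform_inter(self):
        from otuclubs.clubs import Club

        masked = block_masked([3, 3], intra=0.5, inter={(0, 1): -0.1})
        net, part = self.make(
            masked,
            [
                Club(["otu0", "otu1", "otu2"], "otu0", 0),
                Club(["otu3", "otu4", "otu5"], "otu3", 1),
            ],
        )
        stats = club_stats(net, part)
        mean, sd, n = stats.inter[(0, 1)]
        assert mean == pytest.approx(-0.1)
        assert sd == pytest.approx(0.0)
        assert n == 9

    def test_masked_zero_excluded_from_mean(self):
        from otuclubs.clubs import Club

        masked = np.zeros((3, 3))
        masked[0, 1] = masked[1, 0] = 0.2
        masked[0, 2] = masked[2, 0] = 0.4
        # pair (1, 2) is masked to zero -> excluded
        net, part = self.make(masked, [Club(["otu0", "otu1", "otu2"], "otu0", 0)])
        stats = club_stats(net, part)
        mean, sd, n = stats.intra[0]
        assert mean == pytest.approx(0.3)
        assert n == 2

    def test_no_nonzero_inter_is_undefined(self):
        from otuclubs.clubs import Club

        masked = block_masked([3, 3], intra=0.5)  # no cross edges
        net, part = self.make(
            masked,
            [
                Club(["otu0", "otu1", "otu2"], "otu0", 0),
                Club(["otu3", "otu4", "otu5"], "otu3", 1),
            ],
        )
        stats = club_stats(net, part)
        mean, sd, n = stats.inter[(0, 1)]
        assert math.isnan(mean) and math.isnan(sd) and n == 0

    def test_unknown_node_error(self):
        from otuclubs.clubs import Club

        masked = block_masked([3])
        net, _ = make_network_from_masked(masked)
        part = ClubPartition([Club(["otu0", "otu1", "ghost"], "otu0", 0)], [])
        with pytest.raises(ValueError, match="ghost"):
            club_stats(net, part)


class TestFindRivalClubs:
    def test_planted_rival_recovered(self):
        spec = CommunitySpec(
            seed=1,
            clubs=((8, 0.6),) * 4,
            rival_pairs=(((0, 1), -0.3),),
        )
        net, f, truth = pipeline_partition(spec)
        rivals = find_rival_clubs(net)
        assert len(rivals) == 1
        got = {frozenset(rivals[0].club_a), frozenset(rivals[0].club_b)}
        t0 = frozenset(o for o, k in truth.club_of.items() if k == 0)
        t1 = frozenset(o for o, k in truth.club_of.items() if k == 1)
        # each reported club is dominated by one planted block
        for club in got:
            overlap = max(len(club & t0), len(club & t1))
            assert overlap >= 0.8 * min(len(club), 8)
        assert rivals[0].inter_mean < 0

    def test_all_positive_network_no_rivals(self):
        masked = block_masked([5, 5], intra=0.6, inter={(0, 1): 0.3})
        net, _ = make_network_from_masked(masked)
        assert find_rival_clubs(net) == []

    def test_sign_flip_creates_rival(self):
        base = block_masked([5, 5], intra=0.7, inter={(0, 1): 0.3})
        net_pos, _ = make_network_from_masked(base)
        assert find_rival_clubs(net_pos) == []
        flipped = block_masked([5, 5], intra=0.7, inter={(0, 1): -0.3})
        net_neg, _ = make_network_from_masked(flipped)
        rivals = find_rival_clubs(net_neg)
        assert len(rivals) == 1
        assert set(rivals[0].club_a) == {f"otu{i}" for i in range(5)}
        assert set(rivals[0].club_b) == {f"otu{i}" for i in range(5, 10)}
        assert rivals[0].inter_mean == pytest.approx(-0.3)
        assert rivals[0].neg_fraction == 1.0

    def test_rival_invariants(self):
        flipped = block_masked([4, 4], intra=0.7, inter={(0, 1): -0.25})
        net, _ = make_network_from_masked(flipped)
        for r in find_rival_clubs(net):
            assert r.inter_mean < 0
            assert not set(r.club_a) & set(r.club_b)
            assert r.neg_fraction >= 0.5

    def test_phase2_agrees_with_find_clubs_on_single_superclub(self):
        flipped = block_masked([5, 5], intra=0.7, inter={(0, 1): -0.3})
        net, _ = make_network_from_masked(flipped)
        part = find_clubs(net)
        rivals = find_rival_clubs(net)
        clubs_a = {frozenset(c.members) for c in part.clubs}
        clubs_b = {frozenset(rivals[0].club_a), frozenset(rivals[0].club_b)}
        assert clubs_a == clubs_b

    def test_edgeless_network(self):
        net, _ = make_network_from_masked(np.zeros((4, 4)))
        assert find_rival_clubs(net) == []

    def test_min_inter_coverage_respected(self):
        # only 40% of cross member pairs carry a significant correlation
        masked = block_masked([5, 5], intra=0.7)
        rng = np.random.default_rng(0)
        cross = np.zeros((5, 5))
        picks = rng.choice(25, size=10, replace=False)
        cross.flat[picks] = -0.4
        masked[:5, 5:] = cross
        masked[5:, :5] = cross.T
        net, _ = make_network_from_masked(masked)
        assert find_rival_clubs(net, min_inter_coverage=0.5) == []
        found = find_rival_clubs(net, min_inter_coverage=0.3)
        assert len(found) == 1
        assert found[0].inter_mean == pytest.approx(-0.4)

    def test_neg_fraction_threshold_respected(self):
        # cross block half positive, half negative, mean slightly negative
        masked = block_masked([4, 4], intra=0.7)
        cross = np.full((4, 4), 0.2)
        cross[:, :2] = -0.25
        masked[:4, 4:] = cross
        masked[4:, :4] = cross.T
        net, _ = make_network_from_masked(masked)
        assert find_rival_clubs(net, neg_fraction=0.9) == []


class TestWriters:
    def test_tsv_outputs(self, tmp_path):
        masked = block_masked([4, 4], intra=0.7, inter={(0, 1): -0.3})
        net, _ = make_network_from_masked(masked)
        part = find_clubs(net)
        rivals = find_rival_clubs(net)
        write_clubs_tsv(part, tmp_path / "clubs.tsv")
        write_rivals_tsv(rivals, tmp_path / "rivals.tsv")
        write_club_summary_tsv(net, part, tmp_path / "summary.tsv")
        clubs_text = (tmp_path / "clubs.tsv").read_text().splitlines()
        assert clubs_text[0] == "otu_id\tclub_id\tis_leader"
        assert len(clubs_text) - 1 == net.number_of_nodes()
        rivals_text = (tmp_path / "rivals.tsv").read_text().splitlines()
        assert len(rivals_text) - 1 == len(rivals) == 1
        summary = (tmp_path / "summary.tsv").read_text().splitlines()
        assert len(summary) - 1 == len(part.clubs)
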