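import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from pollinet import phylo
from pollinet.network import NetworkInputError
from pollinet.phylo import DegenerateNullError

BALANCED = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture(scope="module")
def balanced_dist():
    return phylo.cophenetic_distances(phylo.load_tree(BALANCED, is_path=False))


class TestCopheneticDistances:
    def test_balanced_tree_path_sums(self, balanced_dist):
        assert balanced_dist.loc["A", "B"] == 2.0
        assert balanced_dist.loc["A", "C"] == 4.0
        assert np.allclose(balanced_dist, balanced_dist.T)
        assert np.diag(balanced_dist).tolist() == [0.0] * 4

    def test_two_leaf_tree(self):
        d = phylo.cophenetic_distances(phylo.load_tree("(A:0.5,B:1.5);", is_path=False))
        assert d.loc["A", "B"] == 2.0

    def test_unlabeled_internal_nodes_tolerated(self):
        d = phylo.cophenetic_distances(
            phylo.load_tree("((A:1,B:1)x:1,C:2)root;", is_path=False)
        )
        assert d.loc["A", "C"] == 4.0

    def test_missing_branch_lengths_rejected_without_flag(self):
        with pytest.raises(NetworkInputError):
            phylo.cophenetic_distances(phylo.load_tree("((A,B),C);", is_path=False))
        d = phylo.cophenetic_distances(
            phylo.load_tree("((A,B),C);", is_path=False),
            allow_missing_lengths=True,
        )
        assert d.loc["A", "B"] == 2.0


class TestSesPhylo:
    def test_exhaustive_pair_example(self, balanced_dist):
        """Sample {A,B} on the balanced tree against all 6 pairs: MPD 2,
        null mean 10/3, population sd 0.9428, SES -1.414 (clustered)."""
        res = phylo.ses_phylo(["A", "B"], list("ABCD"), balanced_dist,
                              stat="MPD", method="exhaustive")
        assert res.observed == 2.0
        assert res.null_mean == pytest.approx(10 / 3)
        assert res.null_sd == pytest.approx(0.9428, abs=1e-4)
        assert res.ses == pytest.approx(-1.414, abs=1e-3)
        assert res.nri_nti == pytest.approx(1.414, abs=1e-3)
        assert res.p_rank == pytest.approx(3 / 7)  # 2 ties at distance 2

    def test_mntd_equals_mpd_for_pairs(self, balanced_dist):
        mpd = phylo.ses_phylo(["A", "C"], list("ABCD"), balanced_dist,
                              stat="MPD", method="exhaustive")
        mntd = phylo.ses_phylo(["A", "C"], list("ABCD"), balanced_dist,
                               stat="MNTD", method="exhaustive")
        assert mpd.observed == mntd.observed == 4.0

    def test_sample_equal_to_pool_is_degenerate(self, balanced_dist):
        with pytest.raises(DegenerateNullError):
            phylo.ses_phylo(list("ABCD"), list("ABCD"), balanced_dist)

    def test_negative_weights_rejected(self, balanced_dist):
        with pytest.raises(NetworkInputError):
            phylo.ses_phylo(["A", "B"], list("ABCD"), balanced_dist,
                            weights=[1, -1, 1, 1], n_null=10)

    def test_weighted_sampling_frequencies_track_weights(self):
        rng = np.random.default_rng(0)
        weights = np.array([8.0, 4.0, 2.0, 1.0, 1.0, 1.0])
        n_null = 20_000
        draws = phylo.null_draws(6, 2, n_null, weights=weights, seed=1)
        freq = np.bincount(draws.ravel(), minlength=6) / (2 * n_null)
        # sequential weighted sampling: first-draw inclusion ~ w_i, check
        # ordering and rough proportionality of inclusion frequencies
        assert list(np.argsort(-freq)[:2]) == [0, 1]
        assert freq[0] > 2.5 * freq[3]

    def test_uniform_ses_calibrated(self):
        """Random samples under uniform nulls: SES has mean ~0, sd ~1."""
        rng = np.random.default_rng(3)
        n_pool = 30
        pts = rng.random((n_pool, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        pool = [f"s{i}" for i in range(n_pool)]
        dist = pd.DataFrame(d, index=pool, columns=pool)
        null = phylo.sample_stat(
            dist.to_numpy(), phylo.null_draws(n_pool, 5, 4000, seed=5), "MPD"
        )
        ses = []
        for rep in range(300):
            sample = rng.choice(pool, size=5, replace=False)
            res = phylo.ses_phylo(sample, pool, dist, stat="MPD",
                                  null_values=null)
            ses.append(res.ses)
        assert abs(np.mean(ses)) < 3 / np.sqrt(300)
        assert 0.8 < np.std(ses) < 1.2


class TestComdist:
    def test_cross_clade_mean(self, balanced_dist):
        assert phylo.comdist(["A", "B"], ["C", "D"], balanced_dist) == 4.0

    def test_symmetry_and_self(self, balanced_dist):
        assert phylo.comdist(["A", "B"], ["C"], balanced_dist) == phylo.comdist(
            ["C"], ["A", "B"], balanced_dist
        )
        assert phylo.comdist(["A"], ["A"], balanced_dist) == 0.0

    def test_community_vs_itself_star_tree(self):
        n = 4
        star = "(" + ",".join(f"L{i}:1" for i in range(n)) + ");"
        d = phylo.cophenetic_distances(phylo.load_tree(star, is_path=False))
        comm = [f"L{i}" for i in range(n)]
        assert phylo.comdist(comm, comm, d) == pytest.approx(2 * (n - 1) / n)

    def test_matches_direct_double_loop(self, balanced_dist):
        comm = list("ABCD")
        direct = np.mean(
            [balanced_dist.loc[a, b] for a in comm for b in comm]
        )
        assert phylo.comdist(comm, comm, balanced_dist) == pytest.approx(direct)


class TestAnosim:
    @staticmethod
    def toy_distance(within, between):
        mat = np.full((4, 4), 0.0)
        mat[0, 1] = mat[1, 0] = within[0]
        mat[2, 3] = mat[3, 2] = within[1]
        pairs = [(0, 2), (0, 3), (1, 2), (1, 3)]
        for (i, j), v in zip(pairs, between):
            mat[i, j] = mat[j, i] = v
        return mat

    def test_maximal_separation_r_is_one(self):
        mat = self.toy_distance([1, 2], [3, 4, 5, 6])
        r, p = phylo.anosim(mat, ["x", "x", "y", "y"], n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_hand_ranked_case_with_ties(self):
        # distances 1,(2.5,2.5 tie),4,5,6 -> R = (4.375-1.75)/3 = 0.875
        mat = self.toy_distance([1, 3], [3, 4, 5, 6])
        r, _ = phylo.anosim(mat, ["x", "x", "y", "y"], n_perm=9, seed=0)
        assert r == pytest.approx(0.875)

    def test_random_groups_center_near_zero(self):
        rng = np.random.default_rng(2)
        pts = rng.random((12, 3))
        mat = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        rs = []
        for rep in range(60):
            groups = rng.permutation(["x"] * 6 + ["y"] * 6)
            r, _ = phylo.anosim(mat, list(groups), n_perm=9, seed=rep)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.1

    def test_group_of_one_rejected(self):
        mat = self.toy_distance([1, 2], [3, 4, 5, 6])
        with pytest.raises(NetworkInputError):
            phylo.anosim(mat, ["x", "y", "y", "y"])

    def test_agrees_with_skbio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(0, 1, (5, 2)), rng.normal(2, 1, (5, 2))])
        mat = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        groups = ["a"] * 5 + ["b"] * 5
        r_ours, _ = phylo.anosim(mat, groups, n_perm=99, seed=0)
        dm = skbio_stats.DistanceMatrix(mat, ids=[str(i) for i in range(10)])
        res = skbio_stats.anosim(dm, grouping=groups, permutations=99)
        assert r_ours == pytest.approx(res["test statistic"], abs=1e-12)


class TestAgainstRPicante:
    """Independent oracle: ape/picante via Rscript on a random tree."""

    def test_cophenetic_mpd_mntd_comdist_match_r(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        from pollinet.synthetic import gen_tree

        tree, _ = gen_tree(4, 3, seed=5)
        nwk = tmp_path / "t.nwk"
        tree.write(path=str(nwk), schema="newick", suppress_rooting=True,
                   unquoted_underscores=True)
        dist = phylo.cophenetic_distances(tree)
        leaves = list(dist.index)
        comm = pd.DataFrame(
            [[1] * 6 + [0] * 6, [0] * 6 + [1] * 6],
            index=["c1", "c2"], columns=leaves,
        )
        comm_path = tmp_path / "comm.csv"
        comm.to_csv(comm_path)
        script = textwrap.dedent(f"""
            suppressMessages(library(picante))
            tr <- read.tree("{nwk}")
            d <- cophenetic(tr)
            comm <- as.matrix(read.csv("{comm_path}", row.names=1, check.names=FALSE))
            d <- d[colnames(comm), colnames(comm)]
            cat(mpd(comm, d), "\\n")
            cat(mntd(comm, d), "\\n")
            cat(as.numeric(comdist(comm, d)), "\\n")
            write.csv(d, "{tmp_path}/rdist.csv")
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        lines = [line.split() for line in out.stdout.strip().splitlines()]
        r_mpd = [float(x) for x in lines[0]]
        r_mntd = [float(x) for x in lines[1]]
        r_comdist = float(lines[2][0])
        rdist = pd.read_csv(tmp_path / "rdist.csv", index_col=0)
        assert np.allclose(rdist.to_numpy(), dist.to_numpy(), atol=1e-8)
        c1, c2 = leaves[:6], leaves[6:]
        d_np = dist.to_numpy()
        idx = {s: i for i, s in enumerate(leaves)}
        mpd1 = phylo.sample_stat(d_np, np.array([idx[s] for s in c1]), "MPD")[0]
        mntd2 = phylo.sample_stat(d_np, np.array([idx[s] for s in c2]), "MNTD")[0]
        # Rscript's cat() prints 7 significant digits
        assert mpd1 == pytest.approx(r_mpd[0], rel=1e-6)
        assert mntd2 == pytest.approx(r_mntd[1], rel=1e-6)
        assert phylo.comdist(c1, c2, dist) == pytest.approx(r_comdist, rel=1e-6)
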