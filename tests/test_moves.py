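"""Generalized move set: hand examples, bulk invariants, oracles."""

import numpy as np
import pytest

from latticefold import (
    DEFAULT_TRY_RATES,
    MoveStats,
    ProteinModel,
    TryRates,
    chain_growth,
    crankshaft,
    end_move,
    hp_potential,
    is_self_avoiding,
    kink_jump,
    linear_build,
    make_lattice,
    pivot_move,
    pull_move,
    pull_step_constant,
    random_move,
    random_walk_build,
    slithering_snake,
)
from latticefold.moves import _pull_candidates
from latticefold.optimizers import CgConfig


def apply_outcome(model, outcome):
    return ProteinModel(model.sequence, model.lattice, outcome.new_coords)


# ---------------------------------------------------------------------------
# hand-checked examples


def test_end_move_straight_trimer(square2, rng):
    m = ProteinModel("HHH", square2, [(0, 0), (1, 0), (2, 0)])
    # free vertices adjacent to the middle residue (1,0): (1,1), (1,-1);
    # plus nothing else — (0,0) occupied, (2,0) is the mover itself (no-op)
    seen = set()
    for _ in range(50):
        out = end_move(m, "last", rng)
        assert out.applied and out.displaced_count == 1
        seen.add(tuple(out.new_coords[2]))
    assert seen == {(1, 1), (1, -1)}


def test_end_move_two_residues_always_feasible(square2, rng):
    m = ProteinModel("HH", square2, [(0, 0), (1, 0)])
    out = end_move(m, "first", rng)
    assert out.applied


def test_end_move_trapped_terminus(square2, rng):
    # every vertex adjacent to the terminus's neighbour (0,0) is occupied,
    # and the terminus's own position is a no-op: the move is infeasible
    coords = [(0, -1), (0, 0), (1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0)]
    m = ProteinModel("H" * 7, square2, coords)
    out = end_move(m, "first", rng)
    assert not out.applied


def test_kink_jump_corner_unique_candidate(square2, rng):
    m = ProteinModel("HHH", square2, [(0, 0), (1, 0), (1, 1)])
    out = kink_jump(m, 1, rng)
    assert out.applied
    assert tuple(out.new_coords[1]) == (0, 1)


def test_kink_jump_straight_segment_infeasible(square2, rng):
    out = kink_jump(linear_build(square2, "HHH"), 1, rng)
    assert not out.applied
    with pytest.raises(IndexError):
        kink_jump(linear_build(square2, "HHH"), 0, rng)


def test_kink_jump_triangular_corner(tri2, rng):
    m = ProteinModel("HHH", tri2, [(0, 0), (1, 0), (1, 1)])
    cands = set()
    for _ in range(60):
        out = kink_jump(m, 1, rng)
        if out.applied:
            cands.add(tuple(out.new_coords[1]))
    assert 1 <= len(cands) <= 2
    for v in cands:
        assert tri2.contains_direction(tuple(np.array(v) - m.coords[0]))
        assert tri2.contains_direction(tuple(np.array(v) - m.coords[2]))


def test_crankshaft_u_shape_and_straight(square2, rng):
    u = ProteinModel("HHHH", square2, [(0, 0), (1, 0), (1, 1), (0, 1)])
    out = crankshaft(u, 0, rng)
    assert out.applied
    assert tuple(out.new_coords[0]) == (0, 0)
    assert tuple(out.new_coords[3]) == (0, 1)
    assert is_self_avoiding(apply_outcome(u, out))
    assert not crankshaft(linear_build(square2, "HHHH"), 0, rng).applied


def test_snake_displaces_whole_chain(square2, rng):
    m = linear_build(square2, "HHH")
    out = slithering_snake(m, "last", rng)
    assert out.applied
    assert out.displaced_count == 3
    assert is_self_avoiding(apply_outcome(m, out))


def test_snake_blocked_end(square2, rng):
    coords = [(1, -1), (1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (0, 0)]
    m = ProteinModel("H" * 9, square2, coords)
    assert not slithering_snake(m, "last", rng).applied


def test_pivot_straightens_l_shape(square2, rng):
    m = ProteinModel("HHH", square2, [(0, 0), (1, 0), (1, 1)])
    out = pivot_move(m, 1, "forward", (1, 0), rng)
    assert out.applied
    assert out.new_coords.tolist() == [[0, 0], [1, 0], [2, 0]]


def test_pivot_identity_direction_rejected(square2, rng):
    m = ProteinModel("HHH", square2, [(0, 0), (1, 0), (1, 1)])
    out = pivot_move(m, 1, "forward", (0, 1), rng)  # current first-step direction
    assert not out.applied


def test_pull_step_constants():
    assert pull_step_constant(make_lattice("square", 2)) == 2
    assert pull_step_constant(make_lattice("square", 4)) == 2
    assert pull_step_constant(make_lattice("triangular", 2)) == 1
    assert pull_step_constant(make_lattice("triangular", 3)) == 1


def test_pull_square_six_mer_semi_local(square2, rng):
    m = linear_build(square2, "HHHHHH")
    cands = _pull_candidates(m, 2, "forward")
    assert cands  # diagonal destinations exist
    out = pull_move(m, 2, "forward", cands[0], rng)
    assert out.applied
    assert out.displaced_count < len(m)
    assert is_self_avoiding(apply_outcome(m, out))


def test_pull_triangular_single_residue_case(tri2, rng):
    """With nu = 1 a destination adjacent to both the target and the next
    branch residue relocates a single residue (kink-jump-like)."""
    m = ProteinModel("HHH", tri2, [(0, 0), (1, 0), (2, 0)])
    out = pull_move(m, 2, "backward", (2, -1), rng)
    assert out.applied
    assert out.displaced_count == 1
    assert tuple(out.new_coords[2]) == (2, -1)
    # interior target whose branch must follow: two residues displaced
    out2 = pull_move(m, 1, "forward", (1, -1), rng)
    assert out2.applied and out2.displaced_count == 2


def test_pull_rejects_bad_destination(square2, rng):
    m = linear_build(square2, "HHHHHH")
    assert not pull_move(m, 2, "forward", (9, 9), rng).applied
    occupied = tuple(m.coords[0])
    assert not pull_move(m, 2, "forward", occupied, rng).applied


# ---------------------------------------------------------------------------
# bulk invariants


@pytest.mark.parametrize(
    "kind, dim", [("square", 2), ("square", 3), ("triangular", 2), ("triangular", 4)]
)
def test_applied_moves_preserve_walk_invariants(kind, dim, rng):
    """Every applied move keeps the sequence, the length and self-avoidance,
    and local moves displace at most two residues."""
    lat = make_lattice(kind, dim)
    seq = "HPHHPPHHHPHH"
    model = random_walk_build(lat, seq, 99)
    stats = MoveStats()
    applied = 0
    for _ in range(2500):
        out = random_move(model, DEFAULT_TRY_RATES, stats, rng)
        if not out.applied:
            continue
        applied += 1
        nxt = apply_outcome(model, out)
        assert is_self_avoiding(nxt)
        assert nxt.sequence == seq and len(nxt) == len(seq)
        assert out.displaced_count >= 1
        assert not np.array_equal(nxt.coords, model.coords)
        if out.move_type in ("end", "kinkjump", "crankshaft"):
            assert out.displaced_count <= 2
        elif out.move_type == "snake":
            assert out.displaced_count == len(seq)
        model = nxt
    assert applied > 500


def enumerate_saws(lattice, n):
    dirs = [tuple(int(x) for x in d) for d in lattice.main_dirs]
    out = []

    def grow(path, occ):
        if len(path) == n:
            out.append(list(path))
            return
        for d in dirs:
            v = tuple(a + b for a, b in zip(path[-1], d))
            if v not in occ:
                occ.add(v)
                path.append(v)
                grow(path, occ)
                path.pop()
                occ.discard(v)

    origin = (0,) * lattice.dim
    grow([origin], {origin})
    return out


def kink_oracle(model, i):
    """Generate-and-test: all single-vertex relocations of residue i that
    keep a valid walk."""
    lat = model.lattice
    cur = tuple(int(x) for x in model.coords[i])
    others = {tuple(int(x) for x in model.coords[j]) for j in range(len(model)) if j != i}
    cands = set()
    for d in lat.main_dirs:
        v = tuple(int(a + b) for a, b in zip(model.coords[i - 1], d))
        if v == cur or v in others:
            continue
        trial = model.coords.copy()
        trial[i] = v
        if is_self_avoiding(ProteinModel(model.sequence, lat, trial)):
            cands.add(v)
    return cands


def crank_oracle(model, i):
    lat = model.lattice
    n = len(model)
    others = {
        tuple(int(x) for x in model.coords[j])
        for j in range(n)
        if j not in (i + 1, i + 2)
    }
    old = (tuple(int(x) for x in model.coords[i + 1]), tuple(int(x) for x in model.coords[i + 2]))
    cands = set()
    for d1 in lat.main_dirs:
        u = tuple(int(a + b) for a, b in zip(model.coords[i], d1))
        if u in others:
            continue
        for d2 in lat.main_dirs:
            v = tuple(int(a + b) for a, b in zip(model.coords[i + 3], d2))
            if v in others or v == u:
                continue
            if not lat.contains_direction(tuple(a - b for a, b in zip(v, u))):
                continue
            if (u, v) == old:
                continue
            cands.add((u, v))
    return cands


def test_exhaustive_kink_and_crank_feasibility_on_short_square_walks(square2, rng):
    """Feasibility of kink-jump and crankshaft on *every* square-lattice
    conformation up to length 6 matches a brute-force generate-and-test
    oracle."""
    for n in (4, 5, 6):
        for coords in enumerate_saws(square2, n):
            m = ProteinModel("H" * n, square2, coords)
            for i in range(1, n - 1):
                oracle = kink_oracle(m, i)
                out = kink_jump(m, i, rng)
                assert out.applied == bool(oracle)
                if out.applied:
                    assert tuple(out.new_coords[i]) in oracle
            for i in range(0, n - 3):
                oracle = crank_oracle(m, i)
                out = crankshaft(m, i, rng)
                assert out.applied == bool(oracle)
                if out.applied:
                    assert (
                        tuple(out.new_coords[i + 1]),
                        tuple(out.new_coords[i + 2]),
                    ) in oracle


def test_local_moves_are_reversible(rng):
    """For applied end/kink/crank/pull moves a move of the same type can
    restore the original conformation (checked constructively)."""
    for kind, dim in [("square", 2), ("triangular", 2)]:
        lat = make_lattice(kind, dim)
        base = random_walk_build(lat, "HPHHPPHHHPHH", 5)
        model = base
        for trial in range(300):
            out = random_move(model, DEFAULT_TRY_RATES, MoveStats(), rng)
            if not out.applied:
                continue
            nxt = apply_outcome(model, out)
            if out.move_type == "end":
                idx = 0 if tuple(nxt.coords[0]) != tuple(model.coords[0]) else len(model) - 1
                restored = {
                    tuple(o.new_coords[idx])
                    for _ in range(80)
                    for o in [end_move(nxt, "first" if idx == 0 else "last", rng)]
                    if o.applied
                }
                assert tuple(model.coords[idx]) in restored
            elif out.move_type == "kinkjump":
                idx = int(np.flatnonzero(np.any(nxt.coords != model.coords, axis=1))[0])
                assert tuple(model.coords[idx]) in kink_oracle(nxt, idx)
            elif out.move_type == "crankshaft":
                first = int(np.flatnonzero(np.any(nxt.coords != model.coords, axis=1))[0])
                # the displaced pair sits at (i+1, i+2); when only the second
                # residue moved the first changed row is i+2
                restored = False
                for idx in (first - 1, first - 2):
                    if 0 <= idx <= len(model) - 4:
                        old = (tuple(model.coords[idx + 1]), tuple(model.coords[idx + 2]))
                        if old in crank_oracle(nxt, idx):
                            restored = True
                assert restored
            elif out.move_type == "pull":
                found = False
                for i in range(len(nxt)):
                    for br in ("forward", "backward"):
                        for cand in _pull_candidates(nxt, i, br):
                            # sweep intermediate-vertex choices deterministically
                            for s_ in range(8):
                                o = pull_move(
                                    nxt, i, br, cand, np.random.default_rng(s_)
                                )
                                if o.applied and np.array_equal(
                                    o.new_coords, model.coords
                                ):
                                    found = True
                assert found, "no pull move restores the previous conformation"
            model = nxt


def test_pull_displacement_concentrated_on_compact_models(rng):
    """Semi-local property: on compact (chain-growth-built) conformations
    the median pull displacement is below N/4."""
    seq = "HPHHPPHHHPHHHPPHHPHHPHPH"
    lat = make_lattice("square", 2)
    model = chain_growth(seq, lat, CgConfig(runs=3, seed=7)).best_model
    disps = []
    for _ in range(3000):
        i = int(rng.integers(len(model)))
        br = ("forward", "backward")[int(rng.integers(2))]
        cands = _pull_candidates(model, i, br)
        if not cands:
            continue
        out = pull_move(model, i, br, cands[int(rng.integers(len(cands)))], rng)
        if out.applied:
            disps.append(out.displaced_count)
    assert len(disps) > 200
    assert np.median(disps) < len(model) / 4


def test_try_rate_sampling_matches_distribution(rng):
    rates = DEFAULT_TRY_RATES
    n = 100_000
    counts = {t: 0 for t in rates.rates}
    for _ in range(n):
        counts[rates.sample(rng)] += 1
    for t, rho in rates.rates.items():
        se = np.sqrt(rho * (1 - rho) / n)
        assert abs(counts[t] / n - rho) < 3 * se + 1e-12


def test_degenerate_rates_and_try_accounting(square2, rng):
    model = random_walk_build(square2, "HPHPHPHP", 3)
    only_pull = TryRates(rates={"pull": 1.0})
    stats = MoveStats()
    for _ in range(200):
        random_move(model, only_pull, stats, rng)
    assert stats.tries["pull"] == 200
    assert sum(stats.tries.values()) == 200
    with pytest.raises(ValueError):
        TryRates(rates={"pull": 0.5})


def test_stats_csv_export(tmp_path):
    stats = MoveStats()
    stats.record_try("pull", True)
    stats.record_improvement("pull")
    path = tmp_path / "stats.csv"
    text = stats.to_csv(path)
    assert path.read_text() == text
    assert "move_type,tries,hits,improvements,h,sigma" in text
    assert stats.hit_rate("pull") == 1.0
    assert stats.sigma("pull") == 1.0
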