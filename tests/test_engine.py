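"""Matching engine: routines, ranking, determinism, caching, dependencies."""

import random

import numpy as np
import pytest

from declops import (
    DenseImage, OpEnvironment, OpInfo, OpMatchError, OpRequest, ParameterSpec,
    Shape, default_environment, rank_candidates, request_key,
)
from declops.engine import Candidate, Sig, op_sig
from declops.errors import DependencyCycleError, ResolutionDepthError
from declops.model import DependencySpec, IORole

from _oracles import (
    BruteForceMatcher, random_environment, random_request, registry_from,
    summarize_tree,
)


def build_env(ops, type_names, edges) -> OpEnvironment:
    env = OpEnvironment(registry=registry_from(type_names, edges))
    env.register(*ops)
    return env


def engine_request(req: dict) -> OpRequest:
    return OpRequest(req["name"], req["shape"], req["in"], out_type=req["out"],
                     container_type=req["container"],
                     mutable_index=req["mutable"])


def engine_summary(env, req):
    try:
        return summarize_tree(env.match(engine_request(req)))
    except OpMatchError:
        return None


class TestDirect:
    def test_single_direct_candidate_no_wrappers(self, env):
        tree = env.match(OpRequest("math.add", Shape.FUNCTION,
                                   ("integer", "integer"), out_type="number"))
        assert tree.root.name == "math.add"
        assert tree.adaptation is None and not tree.conversions

    def test_alias_matches(self, env):
        tree = env.match(OpRequest("engine.create", Shape.FUNCTION,
                                   ("dense-image",), out_type="dense-image"))
        assert "engine.create.like" in tree.root.names

    def test_near_miss_report_covers_routines(self, env):
        with pytest.raises(OpMatchError) as exc:
            env.match(OpRequest("math.add", Shape.FUNCTION, ("text", "text")))
        msg = str(exc.value)
        for routine in ("direct", "adaptation", "conversion"):
            assert routine in msg

    def test_unknown_name_suggests_nearest(self, env):
        with pytest.raises(OpMatchError, match="math.add"):
            env.match(OpRequest("math.ad", Shape.FUNCTION, ("integer", "integer")))


class TestDependencies:
    def test_dog_tree_has_two_gauss_and_one_sub(self, env):
        tree = env.match(OpRequest(
            "filter.dog", Shape.FUNCTION, ("dense-image", "float64", "float64")))
        assert tree.root.name == "filter.dog"
        assert set(tree.dependencies) == {"gauss1", "gauss2", "sub"}
        assert tree.count_nodes("filter.gauss") == 2
        assert tree.count_nodes("math.sub") == 1
        # gauss is a computer matched as a function: adaptation wrapper present
        assert tree.dependencies["gauss1"].adaptation is not None
        # scalar subtraction is lifted element-wise
        assert tree.dependencies["sub"].adaptation.adapter.name == \
            "engine.adapt.lift_elementwise"

    def test_higher_priority_gauss_swaps_dependency_root(self, env):
        req = OpRequest("filter.dog", Shape.FUNCTION,
                        ("dense-image", "float64", "float64"))
        before = env.match(req)
        assert before.dependencies["gauss1"].root.source == \
            "declops.image_ops:gauss"
        better = OpInfo(
            names=("filter.gauss",), shape=Shape.COMPUTER,
            parameters=(
                ParameterSpec("input", "dense-image"),
                ParameterSpec("sigma", "real"),
                ParameterSpec("output", "dense-image", io_role=IORole.CONTAINER),
            ),
            source="fastlib:gauss", priority=100.0,
        )
        env.register(better, implementations={
            "fastlib:gauss": lambda inp, sigma, out: None})
        after = env.match(req)
        assert after.dependencies["gauss1"].root.source == "fastlib:gauss"
        assert after.root == before.root  # dog itself untouched

    def test_self_dependency_cycle_detected(self):
        loop = OpInfo(
            names=("loop.op",), shape=Shape.FUNCTION,
            parameters=(ParameterSpec("x", "T0"),
                        ParameterSpec("out", "T0", io_role=IORole.OUTPUT)),
            source="dummy:loop",
            dependencies=(DependencySpec("self", "loop.op", Shape.FUNCTION),),
        )
        env = build_env([loop], ["T0"], [])
        with pytest.raises(DependencyCycleError, match="loop.op"):
            env.match(OpRequest("loop.op", Shape.FUNCTION, ("T0",)))

    def test_depth_cap(self, monkeypatch):
        monkeypatch.setattr("declops.engine.DEPTH_LIMIT", 3)
        ops = []
        for i in range(6):
            deps = ()
            if i < 5:
                deps = (DependencySpec("next", f"chain.op{i + 1}", Shape.FUNCTION),)
            ops.append(OpInfo(
                names=(f"chain.op{i}",), shape=Shape.FUNCTION,
                parameters=(ParameterSpec("x", "T0"),
                            ParameterSpec("out", "T0", io_role=IORole.OUTPUT)),
                source=f"dummy:c{i}", dependencies=deps,
            ))
        env = build_env(ops, ["T0"], [])
        with pytest.raises(ResolutionDepthError):
            env.match(OpRequest("chain.op0", Shape.FUNCTION, ("T0",)))

    def test_wildcard_dependency_matches_by_name_and_shape(self):
        helper = OpInfo(
            names=("util.id",), shape=Shape.FUNCTION,
            parameters=(ParameterSpec("x", "T0"),
                        ParameterSpec("out", "T0", io_role=IORole.OUTPUT)),
            source="dummy:ident")
        outer = OpInfo(
            names=("alg.outer",), shape=Shape.FUNCTION,
            parameters=(ParameterSpec("x", "T0"),
                        ParameterSpec("out", "T0", io_role=IORole.OUTPUT)),
            source="dummy:outer",
            dependencies=(DependencySpec("f", "util.id", Shape.FUNCTION),))
        env = build_env([helper, outer], ["T0"], [])
        tree = env.match(OpRequest("alg.outer", Shape.FUNCTION, ("T0",)))
        assert tree.dependencies["f"].root == helper


class TestRanking:
    def _cand(self, priority, n_conv, source):
        info = OpInfo(
            names=("x.y",), shape=Shape.FUNCTION,
            parameters=(ParameterSpec("a", "T0"),
                        ParameterSpec("out", "T0", io_role=IORole.OUTPUT)),
            source=source, priority=priority)
        conv_info = OpInfo(
            names=("engine.convert.c",), shape=Shape.FUNCTION,
            parameters=(ParameterSpec("a", "T0"),
                        ParameterSpec("out", "T0", io_role=IORole.OUTPUT)),
            source="dummy:conv")
        from declops.engine import _ConvNeed
        convs = {i: _ConvNeed(forward=conv_info) for i in range(n_conv)}
        return Candidate(root=info, routine="direct", sig=op_sig(info),
                         conversions=convs)

    def test_priority_beats_everything(self):
        lo, hi = self._cand(0.0, 0, "m:a"), self._cand(100.0, 2, "m:b")
        assert rank_candidates([lo, hi])[0] is hi

    def test_fewer_wrappers_break_priority_ties(self):
        many, none = self._cand(1.0, 2, "m:a"), self._cand(1.0, 0, "m:b")
        assert rank_candidates([many, none])[0] is none

    def test_source_breaks_remaining_ties(self):
        a, b = self._cand(0.0, 0, "m:aaa"), self._cand(0.0, 0, "m:bbb")
        assert rank_candidates([b, a])[0] is a

    def test_order_invariant_under_input_permutation(self, rng):
        cands = [self._cand(float(rng.integers(0, 3)), int(rng.integers(0, 3)),
                            f"m:s{i}") for i in range(20)]
        ranked = [c.root.source for c in rank_candidates(cands)]
        for seed in range(5):
            shuffled = list(cands)
            random.Random(seed).shuffle(shuffled)
            assert [c.root.source for c in rank_candidates(shuffled)] == ranked


class TestRoutinePrecedence:
    def test_direct_beats_adapted_and_converted(self):
        """A direct image-level op wins even when a high-priority scalar op
        could be lifted to the same signature."""
        env = default_environment()
        direct_sub = OpInfo(
            names=("math.sub",), shape=Shape.FUNCTION,
            parameters=(
                ParameterSpec("a", "dense-image"),
                ParameterSpec("b", "dense-image"),
                ParameterSpec("out", "dense-image", io_role=IORole.OUTPUT)),
            source="imagelib:sub", priority=-5.0)  # lower priority than scalar
        env.register(direct_sub, implementations={
            "imagelib:sub": lambda a, b: DenseImage(a.values - b.values)})
        tree = env.match(OpRequest("math.sub", Shape.FUNCTION,
                                   ("dense-image", "dense-image")))
        assert tree.root.source == "imagelib:sub"
        assert tree.adaptation is None

    def test_without_base_ops_no_adaptation_or_conversion(self):
        """Dog-fooding: dropping the engine-support descriptors removes the
        adaptation and conversion routines entirely."""
        env = default_environment(include=("image.yaml",))
        with pytest.raises(OpMatchError):
            env.match(OpRequest("filter.gauss", Shape.FUNCTION,
                                ("dense-image", "float64")))
        with pytest.raises(OpMatchError):
            env.match(OpRequest("filter.gauss", Shape.COMPUTER,
                                ("planar-image", "float64"),
                                container_type="planar-image"))


class TestOracleEquivalence:
    def test_match_agrees_with_bruteforce_enumerator(self):
        """Random <=10-op environments with random type DAGs: the engine and
        the exhaustive enumerator select the same candidate (or both fail)."""
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(40):
            ops, types, edges = random_environment(rng)
            env = build_env(ops, types, edges)
            oracle = BruteForceMatcher(ops, types, edges)
            for _ in range(5):
                req = random_request(rng, types)
                assert engine_summary(env, req) == oracle.match(req)
                checked += 1
        assert checked == 200

    def test_registration_order_never_changes_the_match(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            ops, types, edges = random_environment(rng)
            requests = [random_request(rng, types) for _ in range(10)]
            baseline = None
            for seed in range(4):
                shuffled = list(ops)
                random.Random(seed).shuffle(shuffled)
                env = build_env(shuffled, types, edges)
                results = [engine_summary(env, r) for r in requests]
                if baseline is None:
                    baseline = results
                else:
                    assert results == baseline


class TestCache:
    def test_repeated_request_returns_equal_tree(self, env):
        req = OpRequest("filter.dog", Shape.FUNCTION,
                        ("dense-image", "float64", "float64"))
        assert env.match_cached(req) == env.match_cached(req)

    def test_registration_invalidates(self, env):
        req = OpRequest("math.add", Shape.FUNCTION, ("integer", "integer"))
        first = env.match_cached(req)
        better = OpInfo(
            names=("math.add",), shape=Shape.FUNCTION,
            parameters=(ParameterSpec("a", "number"),
                        ParameterSpec("b", "number"),
                        ParameterSpec("out", "number", io_role=IORole.OUTPUT)),
            source="fastlib:add", priority=50.0)
        env.register(better, implementations={"fastlib:add": lambda a, b: a + b})
        second = env.match_cached(req)
        assert second.root.source == "fastlib:add"
        assert second != first
        env.unregister(better)
        assert env.match_cached(req) == first

    def test_cold_warm_equivalence_with_interleaved_mutations(self):
        """Replaying request sequences with the cache on equals a cache-off
        twin environment, across register/unregister mutations."""
        rng = np.random.default_rng(23)
        ops, types, edges = random_environment(rng)
        extra = OpInfo(
            names=("alg.a",), shape=Shape.FUNCTION,
            parameters=(ParameterSpec("x", types[0]),
                        ParameterSpec("out", types[0], io_role=IORole.OUTPUT)),
            source="dummy:extra", priority=99.0)
        warm = build_env(ops, types, edges)
        cold = build_env(ops, types, edges)
        cold.cache_enabled = False
        requests = [random_request(rng, types) for _ in range(30)]
        for i, req in enumerate(requests * 2):
            if i == 20:
                warm.register(extra)
                cold.register(extra)
            if i == 40:
                warm.unregister(extra)
                cold.unregister(extra)
            r_warm = self._cached_summary(warm, req)
            r_cold = self._cached_summary(cold, req)
            assert r_warm == r_cold

    @staticmethod
    def _cached_summary(env, req):
        try:
            return summarize_tree(env.match_cached(engine_request(req)))
        except OpMatchError:
            return None


def test_request_key_format(env):
    req = OpRequest("filter.gauss", Shape.COMPUTER, ("dense-image", "float64"),
                    container_type="dense-image")
    assert request_key(req) == \
        "filter.gauss|computer|in=dense-image,float64,dense-image|out=dense-image"
    fn = OpRequest("math.add", Shape.FUNCTION, ("integer", "integer"))
    assert request_key(fn) == "math.add|function|in=integer,integer|out=*"
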