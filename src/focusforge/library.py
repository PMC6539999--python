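"""Sequence profiles, curation rules, exact library diversity and coverage.

The library-building arithmetic is exact end-to-end: diversities are products
of per-position allowed-set sizes computed with arbitrary-precision integers,
never floats, so a 20^30 design space and a 10^8 focused library live on the
same footing.  Curation applies, in declared order: low-frequency removal,
distal-conservative removal, similarity-group collapse, and wild-type
reinstatement; every edit is logged so the curated library can be re-derived
from the raw profile by replaying the log.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

from .errors import CompletenessError, CurationError, SizeGuardError, SpecError

#: similarity groups used for the collapse rule (e.g. S/T, V/I/L)
DEFAULT_SIMILARITY_GROUPS = (frozenset("ST"), frozenset("VIL"))


@dataclass
class ProfilePosition:
    position: int
    wild_type: str
    counts: dict[str, int]

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[str, float]:
        n = self.n
        return {k: v / n for k, v in self.counts.items()}

    @property
    def identities(self) -> tuple[str, ...]:
        return tuple(sorted(self.counts))


@dataclass
class SequenceProfile:
    """Per-position observed identities with counts over an ensemble of designs."""

    positions: list[ProfilePosition]

    def position(self, number: int) -> ProfilePosition:
        for p in self.positions:
            if p.position == number:
                return p
        raise KeyError(number)


@dataclass(frozen=True)
class CurationRules:
    min_frequency: float = 0.05
    similarity_groups: tuple[frozenset, ...] = DEFAULT_SIMILARITY_GROUPS
    distal_conservative_removals: dict = field(default_factory=dict)
    wt_reinstatement_positions: frozenset = frozenset()
    target_size: int | None = None

    def __post_init__(self):
        if not (0 <= self.min_frequency < 1):
            raise ValueError("min_frequency must be in [0, 1)")
        for a, b in itertools.combinations(self.similarity_groups, 2):
            if a & b:
                raise ValueError("similarity groups must be pairwise disjoint")


@dataclass
class LibrarySpec:
    """Curated allowed-identity sets per position, with exact diversity."""

    positions: list[tuple[int, str, tuple[str, ...]]]  # (position, wt, allowed)
    fixed_background: dict[int, str] = field(default_factory=dict)

    def allowed(self, position: int) -> tuple[str, ...]:
        for pos, _, allowed in self.positions:
            if pos == position:
                return allowed
        raise KeyError(position)

    @property
    def diversity(self) -> int:
        return profile_diversity(self)


def compile_profile(models, positions=None) -> SequenceProfile:
    """Count per-position identities over selected design models.

    All models must share the designable position list.  Positions are
    reported by residue number; wild type comes from the scaffold.
    """
    models = list(models)
    if not models:
        raise CompletenessError("no models to profile")

    def keys_of(m):
        return sorted(set(m.designable) | set(m.match_positions))

    if positions is None:
        keys = keys_of(models[0])
        for m in models:
            if keys_of(m) != keys:
                raise CompletenessError(
                    "models disagree on the designable set; pass an explicit "
                    "position list to profile over their union")
        positions = keys
        strict = True
    else:
        strict = False
    out = []
    for key in positions:
        counts: dict[str, int] = {}
        for m in models:
            ident = m.sequence.get(key) or m.match_sequence.get(key)
            if ident is None:
                if strict:
                    raise CompletenessError(
                        f"model {m.model_id} lacks position {key}")
                # not repacked in this model: wild type by definition
                ident = m.scaffold.residues[key].identity
            counts[ident] = counts.get(ident, 0) + 1
        number = key[1] if isinstance(key, tuple) else int(key)
        wt = models[0].scaffold.residues[key].identity if isinstance(key, tuple) else "X"
        out.append(ProfilePosition(number, wt, counts))
    return SequenceProfile(out)


def profile_diversity(spec) -> int:
    """Exact product of per-position identity-set sizes (arbitrary precision)."""
    if isinstance(spec, SequenceProfile):
        sizes = [len(p.counts) for p in spec.positions]
        empties = [p.position for p in spec.positions if not p.counts]
    elif isinstance(spec, LibrarySpec):
        sizes = [len(allowed) for _, _, allowed in spec.positions]
        empties = [pos for pos, _, allowed in spec.positions if not allowed]
    else:
        raise TypeError("expected SequenceProfile or LibrarySpec")
    if not sizes:
        raise SpecError("no positions")
    if empties:
        raise SpecError(f"empty identity set at position(s) {empties}")
    return math.prod(sizes)


def theoretical_diversity(n_positions: int, alphabet_size: int = 20) -> int:
    """Size of the unconstrained design space: alphabet_size ** n_positions."""
    if n_positions < 0:
        raise ValueError("n_positions must be >= 0")
    return alphabet_size**n_positions


def curate(profile: SequenceProfile, rules: CurationRules):
    """Apply the curation rules in declared order; returns (LibrarySpec, log).

    Order: (1) drop identities below ``min_frequency``; (2) drop listed distal
    conservative identities; (3) collapse each similarity group present at a
    position to its highest-frequency member (ties alphabetical); (4) add the
    wild-type identity at the reinstatement positions.  Positions whose allowed
    set reduces to the wild type alone are dropped from the library (not
    diversified).  The log records every edit with its rule.
    """
    log: list[dict] = []
    spec_rows = []
    for p in profile.positions:
        allowed = set(p.counts)
        freqs = p.frequencies
        for ident in sorted(allowed):
            if freqs[ident] < rules.min_frequency:
                allowed.discard(ident)
                log.append({"rule": "low_frequency", "position": p.position,
                            "identity": ident, "frequency": round(freqs[ident], 4)})
        for ident in sorted(rules.distal_conservative_removals.get(p.position, ())):
            if ident in allowed:
                allowed.discard(ident)
                log.append({"rule": "distal_conservative", "position": p.position,
                            "identity": ident})
        for group in rules.similarity_groups:
            present = sorted(group & allowed)
            if len(present) > 1:
                keep = max(present, key=lambda i: (freqs.get(i, 0.0), -ord(i)))
                # tie -> alphabetical: max on (freq, -ord) picks earliest letter
                for ident in present:
                    if ident != keep:
                        allowed.discard(ident)
                        log.append({"rule": "similarity_collapse",
                                    "position": p.position, "identity": ident,
                                    "kept": keep})
        if p.position in rules.wt_reinstatement_positions and p.wild_type not in allowed:
            allowed.add(p.wild_type)
            log.append({"rule": "wt_reinstatement", "position": p.position,
                        "identity": p.wild_type})
        if not allowed:
            raise CurationError(p.position)
        if allowed == {p.wild_type}:
            log.append({"rule": "wild_type_only_dropped", "position": p.position,
                        "identity": p.wild_type})
            continue
        spec_rows.append((p.position, p.wild_type, tuple(sorted(allowed))))
    return LibrarySpec(spec_rows), log


def replay_curation_log(profile: SequenceProfile, log) -> LibrarySpec:
    """Re-derive the curated spec from the raw profile and the curation log."""
    allowed = {p.position: set(p.counts) for p in profile.positions}
    wt = {p.position: p.wild_type for p in profile.positions}
    dropped = set()
    for event in log:
        pos, ident = event["position"], event["identity"]
        if event["rule"] == "wt_reinstatement":
            allowed[pos].add(ident)
        elif event["rule"] == "wild_type_only_dropped":
            dropped.add(pos)
        else:
            allowed[pos].discard(ident)
    rows = [(p.position, wt[p.position], tuple(sorted(allowed[p.position])))
            for p in profile.positions if p.position not in dropped]
    return LibrarySpec(rows)


def coverage_fraction(n_transformants, diversity) -> float:
    """Expected fraction of distinct library members among N transformants.

    Uniform sampling with replacement: 1 - (1 - 1/V)^N, evaluated through
    log1p/expm1 so it is stable for N and V in the 10^8-10^10 range.
    """
    if diversity < 1:
        raise ValueError("diversity must be >= 1")
    if n_transformants < 0:
        raise ValueError("n_transformants must be >= 0")
    if n_transformants == 0:
        return 0.0
    v = float(diversity)
    if v == 1.0:
        return 1.0
    return -math.expm1(float(n_transformants) * math.log1p(-1.0 / v))


def orders_of_magnitude_reduction(space_before, space_after) -> int:
    """round(log10(before / after)); both sizes must be positive."""
    if space_before <= 0 or space_after <= 0:
        raise ValueError("space sizes must be positive")
    return round(math.log10(space_before) - math.log10(space_after))


def mutation_count(variant: dict[int, str], wild_type: dict[int, str],
                   fixed_background: dict[int, str] | None = None,
                   include_fixed: bool = False) -> int:
    """Number of positions where the variant differs from wild type.

    Fixed background mutations (e.g. D286R) are excluded unless
    ``include_fixed`` is set.
    """
    n = 0
    for pos, ident in variant.items():
        if pos not in wild_type:
            raise KeyError(f"no wild-type reference for position {pos}")
        if ident != wild_type[pos]:
            n += 1
    if include_fixed and fixed_background:
        n += len(fixed_background)
    return n


def render_scientific(value: int, sig: int = 2) -> str:
    """Exact integer rendered in scientific notation at ``sig`` figures."""
    if value == 0:
        return "0"
    exp = len(str(abs(value))) - 1
    mant = value / 10**exp
    return f"{mant:.{sig - 1}f}e{exp:+03d}"


def export_library(spec: LibrarySpec, wild_type_sequence: dict[int, str],
                   enumerate_fasta: bool = False, cap: int = 100_000):
    """Export the focused library as a position table and optional enumeration.

    Returns ``(table, records)``: ``table`` is a pandas DataFrame mirroring the
    position/wild-type/allowed layout; ``records`` is a list of Biopython
    ``SeqRecord`` objects enumerating every library member (fixed background
    mutations applied to each) when requested and the diversity is within
    ``cap``, else None.  Record order is deterministic (sorted identity sets,
    positions ascending, rightmost position varying fastest).
    """
    import pandas as pd

    table = pd.DataFrame(
        [{"position": pos, "wild_type": wt, "allowed": "".join(allowed),
          "n_allowed": len(allowed)} for pos, wt, allowed in spec.positions]
    )
    if not enumerate_fasta:
        return table, None
    div = spec.diversity
    if div > cap:
        raise SizeGuardError(
            f"library diversity {div} exceeds the enumeration cap {cap}")
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    base = dict(wild_type_sequence)
    base.update(spec.fixed_background)
    all_positions = sorted(base)
    lib_positions = [pos for pos, _, _ in spec.positions]
    choice_sets = [sorted(spec.allowed(pos)) for pos in lib_positions]
    records = []
    for i, combo in enumerate(itertools.product(*choice_sets)):
        seq = dict(base)
        seq.update(dict(zip(lib_positions, combo)))
        s = "".join(seq[p] for p in all_positions)
        name = "lib_" + "".join(combo)
        records.append(SeqRecord(Seq(s), id=f"{name}_{i:06d}", description=""))
    return table, records
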