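"""Oddball stimulus-sequence design.

A sequence presents items at a fast base rate (10 Hz by default); every
``oddball_every``-th presentation (the 5th, 10th, 15th, ...) is a *deviant*
drawn from a contrasting category, so deviants recur at
``f_base / oddball_every`` = 2 Hz.  Two ways of balancing base and deviant
sets are supported:

``set_size``
    Base and deviant sets have the same number of distinct items (30 each by
    default), so base items repeat more often (16x vs 4x in a 60-s sequence).
``item_repetition``
    Every item, base or deviant, is shown the same number of times (4x),
    which requires a base set four times larger than the deviant set.

Orthogonal attentional task events (brief colour changes to a central cross
or to flanking vertical bars) are scheduled independently of the stimulus
stream and scored behaviourally downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError, SchedulingError, ValidationError

CATEGORIES = ("word", "pseudoword", "nonword")
CONTROL_TYPES = ("set_size", "item_repetition")
DISCRIMINATIONS = ("NWW", "PWW")
TASKS = ("cross", "bars")

_MAX_RETRIES = 10_000


@dataclass(frozen=True)
class StimulusItem:
    """One letter-string stimulus with optional psycholinguistic attributes."""

    label: str
    category: str
    n_letters: int = 5
    attributes: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if self.n_letters < 1:
            raise ValidationError("n_letters must be >= 1")


@dataclass
class StimulusSet:
    """A labelled set of items, all of one category, with unique labels."""

    items: list[StimulusItem]
    set_id: str = ""

    def __post_init__(self) -> None:
        cats = {it.category for it in self.items}
        if len(cats) > 1:
            raise ValidationError(f"mixed categories in set {self.set_id!r}: {cats}")
        labels = [it.label for it in self.items]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"duplicate labels in set {self.set_id!r}")

    @property
    def category(self) -> str:
        return self.items[0].category if self.items else "word"

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)


@dataclass(frozen=True)
class TaskEvent:
    """A brief colour change the participant monitors (go/no-go)."""

    onset_s: float
    duration_s: float = 0.2
    kind: str = "cross_change"
    is_go: bool = True


@dataclass
class SequencePlan:
    """The full timed presentation stream of one stimulation sequence."""

    base_rate_hz: float
    oddball_every: int
    duration_s: float
    fade_in_s: float
    fade_out_s: float
    control_type: str
    discrimination: str
    stream: list[tuple[float, StimulusItem, bool]]
    task: str
    events: list[TaskEvent]
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def oddball_rate_hz(self) -> float:
        return self.base_rate_hz / self.oddball_every

    @property
    def n_presentations(self) -> int:
        return len(self.stream)

    @property
    def deviant_onsets(self) -> np.ndarray:
        return np.array([t for t, _, d in self.stream if d])

    def validate(self) -> None:
        """Check every structural invariant of the plan; raise on violation."""
        n = round(self.duration_s * self.base_rate_hz)
        if len(self.stream) != n:
            raise ValidationError(f"stream length {len(self.stream)} != {n}")
        soa = 1.0 / self.base_rate_hz
        for i, (t, _, deviant) in enumerate(self.stream):
            if abs(t - i * soa) > 1e-9:
                raise ValidationError(f"presentation {i} at {t}, expected {i * soa}")
            if deviant != ((i + 1) % self.oddball_every == 0):
                raise ValidationError(f"deviant flag wrong at position {i + 1}")
        labels = [it.label for _, it, _ in self.stream]
        for a, b in zip(labels, labels[1:]):
            if a == b:
                raise ValidationError(f"immediate repetition of {a!r}")
        for ev in self.events:
            if not (0.0 <= ev.onset_s and ev.onset_s + ev.duration_s <= self.duration_s):
                raise ValidationError("task event outside stimulation window")


@dataclass
class SessionPlan:
    """An ordered, task-blocked list of sequences for one participant."""

    sequences: list[SequencePlan]
    task_order: tuple[str, str]


def _presentation_counts(
    deviants: StimulusSet,
    base: StimulusSet,
    control_type: str,
    n_total: int,
    oddball_every: int,
) -> tuple[dict[str, int], dict[str, int]]:
    """Per-label presentation counts for the deviant and base multisets."""
    n_dev = n_total // oddball_every
    n_base = n_total - n_dev
    if control_type == "set_size":
        if len(base) != len(deviants):
            raise ConfigurationError(
                f"set_size control requires equal set sizes, got "
                f"{len(base)} base vs {len(deviants)} deviants"
            )
    elif control_type == "item_repetition":
        if len(base) != (oddball_every - 1) * len(deviants):
            raise ConfigurationError(
                f"item_repetition control requires |base| = "
                f"{oddball_every - 1}x|deviants|, got {len(base)} vs {len(deviants)}"
            )
    else:
        raise ConfigurationError(f"unknown control type {control_type!r}")
    if n_dev % len(deviants) or n_base % len(base):
        raise ConfigurationError(
            f"{n_dev} deviant and {n_base} base slots do not divide evenly over "
            f"{len(deviants)} and {len(base)} items"
        )
    dev_counts = {it.label: n_dev // len(deviants) for it in deviants}
    base_counts = {it.label: n_base // len(base) for it in base}
    return dev_counts, base_counts


def _schedule_no_repeat(
    slots: list[str],
    pools: dict[str, list[StimulusItem]],
    counts: dict[str, dict[str, int]],
    rng: np.random.Generator,
) -> list[StimulusItem]:
    """Fill role-tagged slots with items, no two adjacent labels equal.

    Shuffle-with-rejection: each attempt shuffles the per-role multisets,
    interleaves them, then repairs adjacent repeats by swapping with a
    random same-role position that resolves the clash.  Bounded retries.
    """
    by_label = {role: {it.label: it for it in pool} for role, pool in pools.items()}
    for _ in range(_MAX_RETRIES):
        seqs: dict[str, list[str]] = {}
        for role, cnt in counts.items():
            labels = [lbl for lbl, c in cnt.items() for _ in range(c)]
            order = rng.permutation(len(labels))
            seqs[role] = [labels[i] for i in order]
        cursors = {role: 0 for role in counts}
        placed: list[tuple[str, int]] = []  # (role, index into seqs[role])
        for role in slots:
            placed.append((role, cursors[role]))
            cursors[role] += 1

        def label_at(i: int) -> str:
            role, j = placed[i]
            return seqs[role][j]

        ok = True
        for i in range(len(placed)):
            if i > 0 and label_at(i) == label_at(i - 1):
                # swap seqs[role][j] with another occurrence of the same role
                role, j = placed[i]
                positions = [k for k, (r, _) in enumerate(placed) if r == role and k != i]
                rng.shuffle(positions)
                fixed = False
                for k in positions:
                    _, jk = placed[k]
                    cand = seqs[role][jk]
                    if cand == label_at(i - 1):
                        continue
                    if i + 1 < len(placed) and cand == label_at(i + 1):
                        continue
                    here = seqs[role][j]
                    if k > 0 and label_at(k - 1) == here:
                        continue
                    if k + 1 < len(placed) and label_at(k + 1) == here:
                        continue
                    seqs[role][jk], seqs[role][j] = here, cand
                    fixed = True
                    break
                if not fixed:
                    ok = False
                    break
        if ok:
            return [by_label[role][seqs[role][j]] for role, j in placed]
    raise SchedulingError(
        f"could not satisfy no-repeat constraint after {_MAX_RETRIES} attempts"
    )


def plan_sequence(
    deviants: StimulusSet,
    base: StimulusSet,
    control_type: str = "set_size",
    task: str = "cross",
    duration_s: float = 60.0,
    f_base: float = 10.0,
    oddball_every: int = 5,
    seed: int = 0,
    fade_in_s: float = 2.0,
    fade_out_s: float = 2.0,
    discrimination: str | None = None,
    events: list[TaskEvent] | None = None,
) -> SequencePlan:
    """Plan one oddball sequence.

    Items appear every ``1/f_base`` s; presentations 5, 10, 15, ... (counted
    from 1) are deviants.  No item is ever immediately repeated.  With the
    defaults a 60-s sequence holds 600 presentations: 480 base and 120
    deviant.  Deterministic for a given seed.
    """
    if task not in TASKS:
        raise ConfigurationError(f"unknown task {task!r}")
    n_total_f = duration_s * f_base
    n_total = round(n_total_f)
    if abs(n_total_f - n_total) > 1e-9 or n_total % oddball_every:
        raise ConfigurationError(
            f"duration x base rate ({n_total_f}) must be an integer multiple "
            f"of oddball_every ({oddball_every})"
        )
    dev_counts, base_counts = _presentation_counts(
        deviants, base, control_type, n_total, oddball_every
    )
    rng = np.random.default_rng(seed)
    slots = [
        "deviant" if (i + 1) % oddball_every == 0 else "base" for i in range(n_total)
    ]
    items = _schedule_no_repeat(
        slots,
        {"deviant": list(deviants), "base": list(base)},
        {"deviant": dev_counts, "base": base_counts},
        rng,
    )
    soa = 1.0 / f_base
    stream = [
        (i * soa, it, (i + 1) % oddball_every == 0) for i, it in enumerate(items)
    ]
    if discrimination is None:
        discrimination = "NWW" if base.category == "nonword" else "PWW"
    plan = SequencePlan(
        base_rate_hz=f_base,
        oddball_every=oddball_every,
        duration_s=duration_s,
        fade_in_s=fade_in_s,
        fade_out_s=fade_out_s,
        control_type=control_type,
        discrimination=discrimination,
        stream=stream,
        task=task,
        events=list(events) if events is not None else [],
        seed=seed,
    )
    plan.validate()
    return plan


def plan_task_events(
    task: str,
    n_events: int = 8,
    duration_s: float = 60.0,
    min_gap_s: float = 1.0,
    p_go: float = 0.5,
    seed: int = 0,
    event_duration_s: float = 0.2,
) -> list[TaskEvent]:
    """Schedule colour-change events uniformly at random with a minimum gap.

    Cross task: every change is a go trial.  Bars task: both bars change
    together with probability ``p_go`` (go), otherwise one side only
    (no-go), left and right equiprobable.
    """
    if task not in TASKS:
        raise ConfigurationError(f"unknown task {task!r}")
    if n_events < 0:
        raise ConfigurationError("n_events must be >= 0")
    if n_events == 0:
        return []
    occupied = n_events * (event_duration_s + min_gap_s)
    slack = duration_s - occupied
    if slack < 0:
        raise SchedulingError(
            f"cannot pack {n_events} events of {event_duration_s}s with "
            f"{min_gap_s}s gaps into {duration_s}s"
        )
    rng = np.random.default_rng(seed)
    starts = np.sort(rng.uniform(0.0, slack, size=n_events))
    starts = starts + np.arange(n_events) * (event_duration_s + min_gap_s)
    events = []
    for t in starts:
        if task == "cross":
            kind, is_go = "cross_change", True
        else:
            if rng.random() < p_go:
                kind, is_go = "bars_both", True
            else:
                kind = "bars_left" if rng.random() < 0.5 else "bars_right"
                is_go = False
        events.append(TaskEvent(onset_s=float(t), duration_s=event_duration_s,
                                kind=kind, is_go=is_go))
    return events


def plan_session(
    stimuli: Mapping[tuple[str, str], tuple[StimulusSet, StimulusSet]],
    n_reps: int = 3,
    task_order: tuple[str, str] = ("cross", "bars"),
    seed: int = 0,
    n_events: int = 8,
    **sequence_kwargs,
) -> SessionPlan:
    """Plan a full session: two task blocks of ``4 conditions x n_reps``.

    ``stimuli`` maps each (discrimination, control_type) cell of the 2x2
    condition grid to its (deviants, base) stimulus sets.  With ``n_reps=3``
    a session holds 24 sequences, 12 per task block; sequence order within
    each block is randomized by the seed.
    """
    if sorted(task_order) != sorted(TASKS):
        raise ConfigurationError(f"task_order must be a permutation of {TASKS}")
    grid = [(d, c) for d in DISCRIMINATIONS for c in CONTROL_TYPES]
    missing = [cell for cell in grid if cell not in stimuli]
    if missing:
        raise ConfigurationError(f"stimuli missing for condition cells: {missing}")
    root = np.random.SeedSequence(seed)
    order_rng = np.random.default_rng(root.spawn(1)[0])
    sequences: list[SequencePlan] = []
    child_seeds = iter(root.generate_state(2 * n_reps * len(grid) * 4))
    for task in task_order:
        block = [cell for cell in grid for _ in range(n_reps)]
        order_rng.shuffle(block)
        for disc, ctrl in block:
            dev, base = stimuli[(disc, ctrl)]
            seq_seed = int(next(child_seeds)) % (2**31)
            ev_seed = int(next(child_seeds)) % (2**31)
            events = plan_task_events(
                task, n_events=n_events, seed=ev_seed,
                duration_s=sequence_kwargs.get("duration_s", 60.0),
            )
            plan = plan_sequence(
                dev, base, control_type=ctrl, task=task, seed=seq_seed,
                discrimination=disc, events=events, **sequence_kwargs,
            )
            sequences.append(plan)
    return SessionPlan(sequences=sequences, task_order=tuple(task_order))


@dataclass
class MatchReport:
    """Per-attribute two-sample t-test comparison between stimulus sets."""

    rows: list[dict]

    @property
    def flagged(self) -> list[str]:
        return [r["attribute"] for r in self.rows if r["mismatch"]]


def validate_matching(
    words: StimulusSet,
    other: StimulusSet,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> MatchReport:
    """Compare psycholinguistic attributes between two sets with t-tests.

    An attribute is flagged as mismatched when p < ``alpha``; well-matched
    pseudoword sets should show no flags, scrambled nonword sets should be
    flagged on neighbourhood/bigram statistics.
    """
    def table(s: StimulusSet) -> dict[str, np.ndarray]:
        keys = None
        cols: dict[str, list[float]] = {}
        for it in s:
            if it.attributes is None:
                raise ValidationError(f"item {it.label!r} has no attributes")
            if keys is None:
                keys = set(it.attributes)
                cols = {k: [] for k in keys}
            elif set(it.attributes) != keys:
                raise ValidationError("inconsistent attribute keys within set")
            for k in keys:
                cols[k].append(float(it.attributes[k]))
        return {k: np.array(v) for k, v in cols.items()}

    a, b = table(words), table(other)
    if set(a) != set(b):
        raise ValidationError("attribute keys differ between sets")
    rows = []
    for k in sorted(a):
        if np.allclose(a[k], b[k]):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(a[k], b[k], equal_var=equal_var)
        rows.append({
            "attribute": k,
            "t": float(t),
            "p": float(p),
            "mean_a": float(a[k].mean()),
            "mean_b": float(b[k].mean()),
            "mismatch": bool(p < alpha),
        })
    return MatchReport(rows)


def demo_stimulus_sets(seed: int = 0) -> dict[tuple[str, str], tuple[StimulusSet, StimulusSet]]:
    """Synthetic placeholder stimulus sets spanning the full condition grid.

    Labels are generated 5-letter strings (not real French items); attribute
    values are drawn to mimic matched pseudowords (same distribution as the
    words) and mismatched scrambled nonwords (near-zero neighbourhood and
    bigram statistics).  Intended for simulation and testing only.
    """
    rng = np.random.default_rng(seed)
    letters = np.array(list("abcdefghijklmnopqrstuvwxyz"))

    def make_labels(n: int, prefix: str) -> list[str]:
        out, seen = [], set()
        while len(out) < n:
            lbl = prefix + "".join(rng.choice(letters, size=4))
            if lbl not in seen:
                seen.add(lbl)
                out.append(lbl)
        return out

    def attrs(neigh_mu: float, bigram_mu: float) -> dict[str, float]:
        return {
            "orthographic_neighbours": float(max(0.0, rng.normal(neigh_mu, 2.0))),
            "bigram_frequency": float(max(0.0, rng.normal(bigram_mu, 3500.0))),
        }

    def make_set(n: int, category: str, prefix: str, neigh: float, bigram: float,
                 set_id: str) -> StimulusSet:
        return StimulusSet(
            [StimulusItem(lbl, category, 5, attrs(neigh, bigram))
             for lbl in make_labels(n, prefix)],
            set_id=set_id,
        )

    words30 = make_set(30, "word", "w", 2.6, 11600.0, "words")
    pw30 = make_set(30, "pseudoword", "p", 2.6, 11600.0, "pw_set1")
    pw120 = make_set(120, "pseudoword", "q", 2.6, 11600.0, "pw_all")
    nw30 = make_set(30, "nonword", "n", 0.1, 6500.0, "nw_set1")
    nw120 = make_set(120, "nonword", "m", 0.1, 6500.0, "nw_all")
    return {
        ("NWW", "set_size"): (words30, nw30),
        ("NWW", "item_repetition"): (words30, nw120),
        ("PWW", "set_size"): (words30, pw30),
        ("PWW", "item_repetition"): (words30, pw120),
    }
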