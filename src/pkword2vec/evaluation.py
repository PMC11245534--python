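"""Pairwise human-evaluation harness.

Two trained models are compared through blinded A/B tasks: each task shows
a probe word and two groups of its five most similar words, one from each
model, in randomized order.  Reviewers vote for the more related group;
scoring maps majority votes back through the hidden assignment and reports

* the *support rate* — the fraction of tasks the regularized model wins by
  majority vote, overall and stratified by word category, prior-knowledge
  coverage, and frequency tertile (majority ties are reported separately
  and excluded from the denominator);

* the *preference skewness* — the adjusted Fisher-Pearson sample skewness
  of the per-task proportion of reviewers choosing the regularized model,
  per frequency tertile.  Preferences concentrated near 1.0 give large
  positive values; comparing tertiles shows whether the advantage grows as
  word frequency falls.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import Vocabulary
from .prior import PriorSource
from .tuning import frequency_tertiles
from .vectors import WordVectors

__all__ = [
    "ComparisonTask",
    "top_k",
    "generate_tasks",
    "save_tasks",
    "load_tasks",
    "read_votes",
    "support_rate",
    "preference_skewness",
]


def top_k(model: WordVectors, probe: str, k: int = 5) -> list[tuple[str, float]]:
    """The ``k`` most similar words to ``probe`` by descending cosine.

    Ties are broken by word id for determinism.  Errors on an unknown probe
    or when fewer than ``k`` other words exist.
    """
    if probe not in model.index:
        raise KeyError(f"unknown probe word {probe!r}")
    if k > len(model) - 1:
        raise ValueError(f"k={k} exceeds vocabulary size minus one")
    unit = model.unit()
    i = model.index[probe]
    sims = unit @ unit[i]
    sims[i] = -np.inf
    order = np.lexsort((np.arange(len(sims)), -sims))[:k]
    return [(model.words[j], float(sims[j])) for j in order]


@dataclass
class ComparisonTask:
    """One blinded A/B comparison: a probe word and two 5-word groups."""

    task_id: int
    probe: str
    group_a: list[str]
    group_b: list[str]
    a_is_pk: bool
    category: str
    stratum: str
    has_prior: bool


def generate_tasks(
    model_pk: WordVectors,
    model_base: WordVectors,
    vocab: Vocabulary,
    n_tasks: int = 1000,
    seed: int = 0,
    k: int = 5,
    priors: Sequence[PriorSource] = (),
    require_disjoint: bool = False,
) -> list[ComparisonTask]:
    """Build a stratified, blinded comparison task set.

    Probes are sampled without replacement, preserving the vocabulary's
    medical / non-medical proportion; each task pairs the two models'
    top-``k`` lists with a per-task randomized A/B assignment.  The same
    seed reproduces the task set (including assignments) exactly.  With
    ``require_disjoint`` probes whose two lists share a word are skipped.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    eligible = [w for w in vocab.words
                if w in model_pk.index and w in model_base.index]
    by_cat: dict[str, list[str]] = {}
    for w in eligible:
        by_cat.setdefault(vocab.categories[vocab.index[w]], []).append(w)
    fractions = {c: len(ws) / len(eligible) for c, ws in by_cat.items()}
    # largest-remainder rounding of per-category task counts
    quotas = {c: int(n_tasks * f) for c, f in fractions.items()}
    remainder = n_tasks - sum(quotas.values())
    for c in sorted(by_cat, key=lambda c: -(n_tasks * fractions[c]) % 1)[:remainder]:
        quotas[c] += 1

    covered = set()
    for src in priors:
        covered.update(src.candidates)
    tertile = frequency_tertiles(vocab)

    probes: list[str] = []
    for cat in sorted(quotas):
        pool = by_cat[cat]
        if quotas[cat] > len(pool):
            raise ValueError(
                f"category {cat!r} has {len(pool)} words, "
                f"cannot sample {quotas[cat]} probes")
        take = rng.choice(len(pool), size=quotas[cat], replace=False)
        probes.extend(pool[i] for i in take)

    tasks: list[ComparisonTask] = []
    for tid, probe in enumerate(probes):
        pk_words = [w for w, _ in top_k(model_pk, probe, k)]
        base_words = [w for w, _ in top_k(model_base, probe, k)]
        if require_disjoint and set(pk_words) & set(base_words):
            continue
        a_is_pk = bool(rng.random() < 0.5)
        group_a, group_b = ((pk_words, base_words) if a_is_pk
                            else (base_words, pk_words))
        vid = vocab.index[probe]
        tasks.append(ComparisonTask(
            task_id=tid,
            probe=probe,
            group_a=group_a,
            group_b=group_b,
            a_is_pk=a_is_pk,
            category=vocab.categories[vid],
            stratum=tertile[probe],
            has_prior=vid in covered,
        ))
    return tasks


def save_tasks(tasks: Sequence[ComparisonTask], blinded_path: str | Path,
               key_path: str | Path | None = None) -> None:
    """Write tasks as JSON lines: a blinded file for reviewers and,
    optionally, a key file retaining the hidden A/B assignment."""
    with open(blinded_path, "w", encoding="utf-8") as fh:
        for t in tasks:
            row = asdict(t)
            del row["a_is_pk"]
            fh.write(json.dumps(row) + "\n")
    if key_path is not None:
        with open(key_path, "w", encoding="utf-8") as fh:
            for t in tasks:
                fh.write(json.dumps(asdict(t)) + "\n")


def load_tasks(key_path: str | Path) -> list[ComparisonTask]:
    tasks = []
    with open(key_path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                tasks.append(ComparisonTask(**json.loads(line)))
    return tasks


def read_votes(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a (task_id, reviewer_id, choice) votes table."""
    votes = pd.read_csv(path, sep=delimiter,
                        names=["task_id", "reviewer_id", "choice"],
                        header=None, comment="#")
    bad = ~votes["choice"].isin(["a", "b"])
    if bad.any():
        raise ValueError(f"malformed choices: {votes.loc[bad, 'choice'].unique()}")
    if votes.duplicated(["task_id", "reviewer_id"]).any():
        raise ValueError("duplicate (task_id, reviewer_id) votes")
    return votes


def _per_task(tasks: Sequence[ComparisonTask], votes: pd.DataFrame) -> pd.DataFrame:
    """Per-task tallies: votes for the regularized model, outcome of the
    majority vote (win / loss / tie / unvoted)."""
    by_id = {t.task_id: t for t in tasks}
    unknown = set(votes["task_id"]) - set(by_id)
    if unknown:
        raise ValueError(f"votes reference unknown tasks: {sorted(unknown)[:5]}")
    counts = votes.groupby("task_id")["choice"].value_counts().unstack(fill_value=0)
    rows = []
    for t in tasks:
        if t.task_id in counts.index:
            n_a = int(counts.loc[t.task_id].get("a", 0))
            n_b = int(counts.loc[t.task_id].get("b", 0))
        else:
            n_a = n_b = 0
        n_pk = n_a if t.a_is_pk else n_b
        n_total = n_a + n_b
        if n_total == 0:
            outcome = "unvoted"
        elif n_pk * 2 > n_total:
            outcome = "win"
        elif n_pk * 2 < n_total:
            outcome = "loss"
        else:
            outcome = "tie"
        rows.append({
            "task_id": t.task_id,
            "category": t.category,
            "stratum": t.stratum,
            "has_prior": t.has_prior,
            "n_votes": n_total,
            "n_pk": n_pk,
            "prop_pk": n_pk / n_total if n_total else np.nan,
            "outcome": outcome,
        })
    return pd.DataFrame(rows)


_STRATIFIERS = ("overall", "category", "has_prior", "stratum")


def support_rate(tasks: Sequence[ComparisonTask],
                 votes: pd.DataFrame) -> pd.DataFrame:
    """Majority-vote support rate for the regularized model, per stratum.

    The rate is wins / (wins + losses); exact ties and unvoted tasks are
    reported in their own columns and excluded from the denominator.
    """
    per_task = _per_task(tasks, votes)
    rows = []
    for strat in _STRATIFIERS:
        groups = ([("all", per_task)] if strat == "overall"
                  else list(per_task.groupby(strat)))
        for level, g in groups:
            wins = int((g["outcome"] == "win").sum())
            losses = int((g["outcome"] == "loss").sum())
            ties = int((g["outcome"] == "tie").sum())
            unvoted = int((g["outcome"] == "unvoted").sum())
            decided = wins + losses
            rows.append({
                "stratifier": strat,
                "level": str(level),
                "n_tasks": len(g),
                "n_ties": ties,
                "n_unvoted": unvoted,
                "support_rate": wins / decided if decided else np.nan,
            })
    return pd.DataFrame(rows)


def preference_skewness(tasks: Sequence[ComparisonTask],
                        votes: pd.DataFrame) -> pd.DataFrame:
    """Adjusted Fisher-Pearson skewness of per-task preference proportions.

    Computed per frequency tertile (and overall) on the proportion of
    reviewers choosing the regularized model per task.  Strong preference
    for that model piles proportions near 1.0, stretching a tail to the
    left: the raw standardized third moment (``skewness``) is then
    negative.  The ``left_skew`` column negates it, so that concentration
    near 1.0 reads as a large positive "left sample skew" — the convention
    under which such results are usually quoted.  A stratum whose
    proportions are all identical has zero third moment and reports 0.
    """
    per_task = _per_task(tasks, votes)
    per_task = per_task[per_task["n_votes"] > 0]
    rows = []
    for strat in ("overall", "stratum"):
        groups = ([("all", per_task)] if strat == "overall"
                  else list(per_task.groupby("stratum")))
        for level, g in groups:
            props = g["prop_pk"].to_numpy()
            if len(props) < 3:
                raise ValueError(
                    f"stratum {level!r} has {len(props)} voted tasks; "
                    "need at least 3 for skewness")
            if np.ptp(props) == 0.0:
                skew = 0.0
            else:
                skew = float(stats.skew(props, bias=False))
            rows.append({
                "stratifier": strat,
                "level": str(level),
                "n_tasks": len(g),
                "mean_prop": float(props.mean()),
                "skewness": skew,
                "left_skew": -skew,
            })
    return pd.DataFrame(rows)
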