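"""Computer-tailored step advice.

The engine turns a participant's diagnostic-questionnaire answers and
pedometer-measured average daily steps into a three-part, individualized
advice document promoting the 10,000 steps/day guideline:

1. a general introduction whose tone is matched to the participant's stage
   of change (transtheoretical model);
2. personalized feedback on the current step level, with a week-by-week
   schedule that raises the daily goal by 500 or 1000 steps per week until
   10,000 steps/day is reached;
3. recommendations selected per psychosocial determinant (theory of planned
   behavior: intentions, attitudes, self-efficacy, social support,
   knowledge, benefits, barriers).

On repeat requests the document additionally contains progress feedback
comparing the previous with the current step level.

All advice text lives in an external message bank (JSON), so wording can be
changed without touching code; the engine itself is pure rule matching and
is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Mapping, Optional, Sequence

STEP_GOAL = 10_000
ALLOWED_INCREMENTS = (500, 1000)
#: months at goal needed before "action" becomes "maintenance"
MAINTENANCE_MONTHS = 6

ATTITUDE_ITEMS = ("healthy", "enjoyable", "good", "relaxing")
ATTITUDE_ANSWERS = ("not_agree", "sometimes", "agree")
SELF_EFFICACY_ITEMS = ("usual_week", "feeling_bad", "busy_schedule")
SELF_EFFICACY_ANSWERS = ("sure_can", "think_can", "sure_cannot")
SUPPORT_PERSONS = ("partner", "children", "friends")
SUPPORT_FREQUENCIES = ("never", "sometimes", "often", "not_applicable")
ACTIVE_STATUSES = ("yes", "no", "not_applicable")
BENEFIT_OPTIONS = (
    "lose_weight",
    "feel_less_depressed",
    "feel_more_attractive",
    "better_physical_condition",
    "meet_new_people",
    "have_fun",
    "feel_the_kick_of_competition",
)
BARRIER_OPTIONS = (
    "lack_of_interest",
    "lack_of_time",
    "lack_of_self_discipline",
    "lack_of_social_support",
    "lack_of_pleasure",
    "external_factors",
    "lack_of_walking_partner",
    "lack_of_good_health",
    "activity_makes_me_tired",
    "having_an_injury",
)
DETERMINANTS = (
    "intentions",
    "attitudes",
    "self_efficacy",
    "social_support",
    "knowledge",
    "benefits",
    "barriers",
)


class StageOfChange(str, Enum):
    """Transtheoretical-model stage used to select advice tone and content."""

    PRECONTEMPLATION = "precontemplation"
    CONTEMPLATION = "contemplation"
    PREPARATION = "preparation"
    ACTION = "action"
    MAINTENANCE = "maintenance"


class StageClassificationError(ValueError):
    """A below-goal participant is missing a required intention answer."""


class MessageLookupError(LookupError):
    """No bank entry matches a (determinant, answer, stage) triple."""

    def __init__(self, determinant: str, answer: str, stage: Optional[str]):
        self.determinant = determinant
        self.answer = answer
        self.stage = stage
        super().__init__(
            f"no message for determinant={determinant!r} "
            f"answer={answer!r} stage={stage!r}"
        )


def _check_choice(value: str, allowed: Sequence[str], what: str) -> None:
    if value not in allowed:
        raise ValueError(f"{what} must be one of {list(allowed)}, got {value!r}")


@dataclass(frozen=True)
class SocialSupportAnswer:
    """One person's (partner/children/friends) support answers."""

    support: str  # never / sometimes / often / not_applicable
    active: str  # yes / no / not_applicable

    def __post_init__(self) -> None:
        _check_choice(self.support, SUPPORT_FREQUENCIES, "support frequency")
        _check_choice(self.active, ACTIVE_STATUSES, "activity status")


@dataclass(frozen=True)
class TailoringResponse:
    """One participant's answers to the diagnostic questionnaire.

    ``avg_daily_steps`` is the researcher-computed pedometer average handed
    to the participant; ``previous_avg_daily_steps`` is supplied on repeat
    advice requests and triggers progress feedback.  The intention answers
    may be ``None`` for participants already at the 10,000-steps goal (they
    are not needed to stage those participants).
    """

    avg_daily_steps: float
    intent_6mo: Optional[str] = None  # yes / no
    intent_1mo: Optional[str] = None  # yes / no
    attitude_items: Mapping[str, str] = field(
        default_factory=lambda: {i: "agree" for i in ATTITUDE_ITEMS}
    )
    self_efficacy_items: Mapping[str, str] = field(
        default_factory=lambda: {i: "think_can" for i in SELF_EFFICACY_ITEMS}
    )
    social_support: Mapping[str, SocialSupportAnswer] = field(
        default_factory=lambda: {
            p: SocialSupportAnswer("sometimes", "yes") for p in SUPPORT_PERSONS
        }
    )
    pedometer_familiarity: str = "yes"  # yes / no
    benefit: str = "better_physical_condition"
    barriers: tuple[str, str] = ("lack_of_time", "external_factors")
    previous_avg_daily_steps: Optional[float] = None
    months_meeting_goal: Optional[float] = None

    def __post_init__(self) -> None:
        if self.avg_daily_steps < 0:
            raise ValueError("avg_daily_steps must be nonnegative")
        for name, val in (("intent_6mo", self.intent_6mo),
                          ("intent_1mo", self.intent_1mo)):
            if val is not None:
                _check_choice(val, ("yes", "no"), name)
        if set(self.attitude_items) != set(ATTITUDE_ITEMS):
            raise ValueError(f"attitude_items must cover {ATTITUDE_ITEMS}")
        for item, ans in self.attitude_items.items():
            _check_choice(ans, ATTITUDE_ANSWERS, f"attitude {item!r}")
        if set(self.self_efficacy_items) != set(SELF_EFFICACY_ITEMS):
            raise ValueError(
                f"self_efficacy_items must cover {SELF_EFFICACY_ITEMS}"
            )
        for item, ans in self.self_efficacy_items.items():
            _check_choice(ans, SELF_EFFICACY_ANSWERS, f"self-efficacy {item!r}")
        if set(self.social_support) != set(SUPPORT_PERSONS):
            raise ValueError(f"social_support must cover {SUPPORT_PERSONS}")
        _check_choice(self.pedometer_familiarity, ("yes", "no"),
                      "pedometer_familiarity")
        _check_choice(self.benefit, BENEFIT_OPTIONS, "benefit")
        if len(self.barriers) != 2 or len(set(self.barriers)) != 2:
            raise ValueError("exactly two distinct barriers are required")
        for b in self.barriers:
            _check_choice(b, BARRIER_OPTIONS, "barrier")
        if (self.previous_avg_daily_steps is not None
                and self.previous_avg_daily_steps < 0):
            raise ValueError("previous_avg_daily_steps must be nonnegative")
        if self.months_meeting_goal is not None and self.months_meeting_goal < 0:
            raise ValueError("months_meeting_goal must be nonnegative")


@dataclass(frozen=True)
class StepSchedule:
    """Week-by-week daily step goals rising to 10,000 steps/day."""

    baseline: float
    increment: int
    weekly_goals: tuple[int, ...]

    @property
    def n_weeks(self) -> int:
        return len(self.weekly_goals)


@dataclass(frozen=True)
class BankEntry:
    id: str
    determinant: str
    answer_pattern: str
    stage: str  # a stage value or "*"
    template: str


class MessageBank:
    """Rule-matched advice text keyed by (determinant, answer pattern, stage).

    Lookup prefers an entry whose ``stage`` matches exactly over a ``"*"``
    wildcard entry.  The default bank shipped with the package covers every
    legal (determinant, answer) pair of the questionnaire.
    """

    def __init__(self, entries: Sequence[BankEntry]):
        self.entries: dict[str, BankEntry] = {}
        self._index: dict[tuple[str, str, str], str] = {}
        for e in entries:
            if e.id in self.entries:
                raise ValueError(f"duplicate message identifier {e.id!r}")
            self.entries[e.id] = e
            key = (e.determinant, e.answer_pattern, e.stage)
            if key in self._index:
                raise ValueError(f"duplicate bank rule {key}")
            self._index[key] = e.id

    @classmethod
    def from_json(cls, path) -> "MessageBank":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        return cls([BankEntry(**e) for e in raw])

    @classmethod
    def default(cls) -> "MessageBank":
        ref = resources.files("steptailor.data").joinpath("message_bank.json")
        raw = json.loads(ref.read_text(encoding="utf-8"))
        return cls([BankEntry(**e) for e in raw])

    def lookup(self, determinant: str, answer: str,
               stage: Optional[StageOfChange] = None) -> str:
        """Return the message identifier for one (determinant, answer) pair."""
        if stage is not None:
            mid = self._index.get((determinant, answer, stage.value))
            if mid is not None:
                return mid
        mid = self._index.get((determinant, answer, "*"))
        if mid is None:
            raise MessageLookupError(
                determinant, answer, stage.value if stage else None
            )
        return mid

    def render(self, message_id: str, **params) -> str:
        return self.entries[message_id].template.format(**params)


def classify_stage(response: TailoringResponse) -> StageOfChange:
    """Classify a participant into a transtheoretical-model stage.

    Below 10,000 steps/day the stage follows the two intention horizons
    (6 months and 1 month); at or above the goal it follows how long the
    goal has been met, with "action" when the duration is unknown.  The
    1-month intention dominates the 6-month answer (the more proximal
    intention decides).
    """
    if response.avg_daily_steps >= STEP_GOAL:
        months = response.months_meeting_goal
        if months is not None and months >= MAINTENANCE_MONTHS:
            return StageOfChange.MAINTENANCE
        return StageOfChange.ACTION
    if response.intent_1mo == "yes":
        return StageOfChange.PREPARATION
    if response.intent_6mo is None:
        raise StageClassificationError(
            "intent_6mo is required for participants below 10,000 steps/day"
        )
    if response.intent_6mo == "no":
        return StageOfChange.PRECONTEMPLATION
    if response.intent_1mo is None:
        raise StageClassificationError(
            "intent_1mo is required when intent_6mo is 'yes'"
        )
    return StageOfChange.CONTEMPLATION


def generate_schedule(baseline: float, increment: int) -> StepSchedule:
    """Build the weekly goal ladder from ``baseline`` up to 10,000 steps/day.

    Week k's daily goal is ``baseline + (k+1) * increment`` capped at
    10,000; the list is empty when the baseline already meets the goal.
    """
    if baseline < 0:
        raise ValueError("baseline must be nonnegative")
    if increment not in ALLOWED_INCREMENTS:
        raise ValueError(
            f"increment must be one of {ALLOWED_INCREMENTS}, got {increment}"
        )
    goals: list[int] = []
    level = baseline
    while level < STEP_GOAL:
        level = min(level + increment, STEP_GOAL)
        goals.append(int(round(level)))
    return StepSchedule(baseline=baseline, increment=increment,
                        weekly_goals=tuple(goals))


def select_determinant_feedback(
    determinant: str,
    response: TailoringResponse,
    stage: StageOfChange,
    bank: MessageBank,
) -> list[str]:
    """Select the message identifiers for one psychosocial determinant.

    Every determinant yields at least one message, except knowledge, where
    the pedometer primer appears only for participants unfamiliar with a
    pedometer.  Barriers yield exactly one message per chosen barrier.
    """
    if determinant == "intentions":
        if response.avg_daily_steps >= STEP_GOAL:
            return [bank.lookup("intentions", "at_goal", stage)]
        if response.intent_1mo == "yes":
            return [bank.lookup("intentions", "1mo:yes", stage)]
        if response.intent_6mo == "yes":
            return [bank.lookup("intentions", "6mo:yes,1mo:no", stage)]
        return [bank.lookup("intentions", "6mo:no", stage)]
    if determinant == "attitudes":
        return [
            bank.lookup("attitudes", f"{item}:{response.attitude_items[item]}",
                        stage)
            for item in ATTITUDE_ITEMS
        ]
    if determinant == "self_efficacy":
        return [
            bank.lookup("self_efficacy",
                        f"{item}:{response.self_efficacy_items[item]}", stage)
            for item in SELF_EFFICACY_ITEMS
        ]
    if determinant == "social_support":
        ids = []
        for person in SUPPORT_PERSONS:
            answer = response.social_support[person]
            ids.append(bank.lookup(
                "social_support", f"support:{person}:{answer.support}", stage))
            ids.append(bank.lookup(
                "social_support", f"active:{person}:{answer.active}", stage))
        return ids
    if determinant == "knowledge":
        if response.pedometer_familiarity == "no":
            return [bank.lookup("knowledge", "familiarity:no", stage)]
        return []
    if determinant == "benefits":
        return [bank.lookup("benefits", response.benefit, stage)]
    if determinant == "barriers":
        return [bank.lookup("barriers", b, stage) for b in response.barriers]
    raise ValueError(f"unknown determinant {determinant!r}")


def _round_half_away(x: float) -> int:
    import math

    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ProgressFeedback:
    delta: int
    variant: str  # improved / unchanged / declined
    text: str


def progress_feedback(previous: float, current: float,
                      bank: Optional[MessageBank] = None) -> ProgressFeedback:
    """Compare the previous with the current step level on a repeat request."""
    if previous < 0 or current < 0:
        raise ValueError("step levels must be nonnegative")
    bank = bank or MessageBank.default()
    delta = _round_half_away(current - previous)
    variant = "improved" if delta > 0 else "declined" if delta < 0 else "unchanged"
    mid = bank.lookup("progress", variant)
    text = bank.render(mid, previous=_round_half_away(previous),
                       current=_round_half_away(current), delta=abs(delta))
    return ProgressFeedback(delta=delta, variant=variant, text=text)


@dataclass(frozen=True)
class AdviceDocument:
    """The three-part tailored step advice."""

    stage: StageOfChange
    introduction: str
    personal_feedback: str
    schedule: StepSchedule
    recommendations: tuple[str, ...]
    determinant_messages: Mapping[str, tuple[str, ...]]
    progress_note: Optional[str] = None

    def to_markdown(self) -> str:
        lines = ["# Your personal step advice", "", "## Introduction", "",
                 self.introduction, ""]
        if self.progress_note:
            lines += ["## Your progress", "", self.progress_note, ""]
        lines += ["## Your steps", "", self.personal_feedback, ""]
        if self.schedule.weekly_goals:
            lines.append("| Week | Daily step goal |")
            lines.append("| --- | --- |")
            for week, goal in enumerate(self.schedule.weekly_goals, start=1):
                lines.append(f"| {week} | {goal} |")
            lines.append("")
        lines += ["## Recommendations", ""]
        for rec in self.recommendations:
            lines.append(f"- {rec}")
        lines.append("")
        return "\n".join(lines)

    def to_html(self) -> str:
        import html

        parts = ["<article class='step-advice'>",
                 "<h1>Your personal step advice</h1>",
                 "<section><h2>Introduction</h2>"
                 f"<p>{html.escape(self.introduction)}</p></section>"]
        if self.progress_note:
            parts.append("<section><h2>Your progress</h2>"
                         f"<p>{html.escape(self.progress_note)}</p></section>")
        parts.append("<section><h2>Your steps</h2>"
                     f"<p>{html.escape(self.personal_feedback)}</p>")
        if self.schedule.weekly_goals:
            rows = "".join(
                f"<tr><td>{w}</td><td>{g}</td></tr>"
                for w, g in enumerate(self.schedule.weekly_goals, start=1)
            )
            parts.append("<table><thead><tr><th>Week</th>"
                         "<th>Daily step goal</th></tr></thead>"
                         f"<tbody>{rows}</tbody></table>")
        parts.append("</section><section><h2>Recommendations</h2><ul>")
        for rec in self.recommendations:
            parts.append(f"<li>{html.escape(rec)}</li>")
        parts.append("</ul></section></article>")
        return "".join(parts)


def compose_advice(response: TailoringResponse,
                   bank: Optional[MessageBank] = None,
                   increment: int = 500) -> AdviceDocument:
    """Compose the full three-part advice document for one participant.

    Deterministic: identical inputs produce byte-identical documents.  The
    introduction is styled by stage; part 2 embeds the current step level
    and the weekly schedule; part 3 concatenates the determinant-matched
    recommendation messages.  A progress note is present exactly when a
    previous step level was supplied.
    """
    bank = bank or MessageBank.default()
    stage = classify_stage(response)
    intro_id = bank.lookup("introduction", "*", stage)
    introduction = bank.render(intro_id)

    schedule = generate_schedule(response.avg_daily_steps, increment)
    steps_out = _round_half_away(response.avg_daily_steps)
    if schedule.weekly_goals:
        fb_id = bank.lookup("personal_feedback", "below_goal", stage)
        personal = bank.render(fb_id, steps=steps_out, increment=increment)
    else:
        fb_id = bank.lookup("personal_feedback", "at_goal", stage)
        personal = bank.render(fb_id, steps=steps_out)

    determinant_messages: dict[str, tuple[str, ...]] = {}
    recommendations: list[str] = []
    for det in DETERMINANTS:
        ids = select_determinant_feedback(det, response, stage, bank)
        determinant_messages[det] = tuple(ids)
        recommendations.extend(bank.render(mid) for mid in ids)

    progress_note = None
    if response.previous_avg_daily_steps is not None:
        progress_note = progress_feedback(
            response.previous_avg_daily_steps, response.avg_daily_steps, bank
        ).text

    return AdviceDocument(
        stage=stage,
        introduction=introduction,
        personal_feedback=personal,
        schedule=schedule,
        recommendations=tuple(recommendations),
        determinant_messages=determinant_messages,
        progress_note=progress_note,
    )
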