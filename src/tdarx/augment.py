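"""Diagnosis-preserving expansion of labelled cohorts.

The study grew its learning set by manual modification: a rheumatologist
cloned each patient's data with free edits that "could not affect the
original diagnosis", expanding every RA patient 1 -> 6 and every nonRA
patient 1 -> 5.  Those manual edits are unknowable, so this module
substitutes an explicit stochastic policy as a reproducible proxy: each
clone jitters continuous values and occasionally flips flags or steps
ultrasound scores, under three hard guards — the label never changes, at
most a bounded number of fields may change their colour category (each by
at most a bounded number of levels on the field's own ordered colour
scale), and protected fields (by default ACPA and RF, the diagnosis-
critical serology) keep their category exactly.

The guards are enforced constructively: a jitter that would illegally
change a field's category is clamped back into the original category's
value interval, so every clone satisfies the policy by construction (and
tests re-verify this through pixel decoding of rendered clones).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .records import (CHANNEL_ATTRS, FLAG_FIELDS, NUMERIC_FIELDS,
                      PatientRecord, iter_joint_keys, joint_field_id,
                      validate_record)
from .rules import Band, NumericRule, RuleSet, default_rules


@dataclass(frozen=True)
class AugmentationPolicy:
    """Bounded-perturbation policy (the identity policy has zero jitter and
    zero allowed category changes)."""

    ra_multiplier: int = 6        # one original -> this many records
    nonra_multiplier: int = 5
    jitter: float = 0.10          # relative jitter for continuous fields
    max_fields_changed: int = 4   # fields allowed to change colour category
    max_category_drift: int = 1   # levels on the field's own colour scale
    protected: tuple[str, ...] = ("acpa", "rf")
    p_flip_flag: float = 0.03     # trunk pain / skin abnormality flips
    p_flip_joint: float = 0.02    # joint symptom/tenderness/swelling flips
    p_step_score: float = 0.05    # GS/PD +-1 steps
    seed: int = 0

    def __post_init__(self):
        if self.ra_multiplier < 1 or self.nonra_multiplier < 1:
            raise ValueError("multipliers must be >= 1")
        if self.max_category_drift < 0 or self.max_fields_changed < 0:
            raise ValueError("drift and change budgets must be >= 0")

    def multiplier(self, label: str) -> int:
        return self.ra_multiplier if label == "RA" else self.nonra_multiplier


def identity_policy(seed: int = 0) -> AugmentationPolicy:
    return AugmentationPolicy(jitter=0.0, max_fields_changed=0,
                              p_flip_flag=0.0, p_flip_joint=0.0,
                              p_step_score=0.0, seed=seed)


_EPS = 1e-9
_DOMAIN_HI = {"patient_vas": 100.0, "doctor_vas": 100.0,
              "body_temperature": 43.0}


def _clamp_into_band(rule: NumericRule, band: Band, v: float,
                     field_id: str) -> float:
    lo = band.lo if band.lo_incl else band.lo + _EPS
    hi = band.hi if band.hi_incl else band.hi - _EPS
    hi = min(hi, _DOMAIN_HI.get(field_id, math.inf))
    return min(max(v, lo), hi)


def perturb_record(record: PatientRecord, policy: AugmentationPolicy,
                   rng: np.random.Generator,
                   rules: RuleSet | None = None) -> PatientRecord:
    """One bounded, label-preserving clone of ``record``."""
    if record.label is None:
        raise ValueError(f"record {record.patient_id} is unlabelled")
    rules = rules or default_rules()
    clone = record.copy()
    budget = policy.max_fields_changed

    # continuous clinical fields, in a seeded random order so budget
    # consumption is unbiased
    order = [NUMERIC_FIELDS[i]
             for i in rng.permutation(len(NUMERIC_FIELDS))]
    for fid in order:
        v = getattr(clone, fid)
        v2 = v * (1.0 + rng.uniform(-policy.jitter, policy.jitter))
        v2 = min(max(v2, 0.0), _DOMAIN_HI.get(fid, math.inf))
        rule = rules.clinical[fid]
        c0, c1 = rule.categorize(v), rule.categorize(v2)
        if c1 is not c0:
            drift = rules.drift(fid, c0, c1)
            if (fid in policy.protected or budget == 0
                    or drift > policy.max_category_drift):
                v2 = _clamp_into_band(rule, rule.band_for(c0), v2, fid)
            else:
                budget -= 1
        setattr(clone, fid, v2)

    # binary clinical flags (gender and demographics are never touched)
    for fid in FLAG_FIELDS:
        if (fid not in policy.protected and budget > 0
                and policy.max_category_drift >= 1
                and rng.random() < policy.p_flip_flag):
            setattr(clone, fid, not getattr(clone, fid))
            budget -= 1

    # joint channels
    for side, site in iter_joint_keys():
        jf = clone.joints[(side, site)]
        for ch in ("a", "b", "c"):
            fid = joint_field_id(side, site, ch)
            if (fid not in policy.protected and budget > 0
                    and policy.max_category_drift >= 1
                    and rng.random() < policy.p_flip_joint):
                attr = CHANNEL_ATTRS[ch]
                setattr(jf, attr, not getattr(jf, attr))
                budget -= 1
        for ch in ("d", "e"):
            fid = joint_field_id(side, site, ch)
            if (fid not in policy.protected and budget > 0
                    and policy.max_category_drift >= 1
                    and rng.random() < policy.p_step_score):
                attr = CHANNEL_ATTRS[ch]
                step = int(rng.choice((-1, 1)))
                v2 = getattr(jf, attr) + step
                # keep scores in range and preserve PD <= GS without
                # touching the other channel (each change is budgeted)
                ok = 0 <= v2 <= 3
                if ch == "d":
                    ok = ok and v2 >= jf.pd_score
                else:
                    ok = ok and v2 <= jf.gs_score
                if ok:
                    setattr(jf, attr, v2)
                    budget -= 1

    if validate_record(clone):  # pragma: no cover - guard of last resort
        return record.copy()
    return clone


def expand_dataset(records: list[PatientRecord],
                   policy: AugmentationPolicy | None = None,
                   rules: RuleSet | None = None) -> list[PatientRecord]:
    """Expand every original into ``multiplier(label)`` records.

    The original is always retained (first in its group); clone ids append
    ``-augN``.  Deterministic given the policy seed and the input order.
    """
    policy = policy or AugmentationPolicy()
    rules = rules or default_rules()
    for r in records:
        if r.label is None:
            raise ValueError(f"record {r.patient_id} is unlabelled")
    rng = np.random.default_rng(policy.seed)
    out: list[PatientRecord] = []
    for record in records:
        out.append(record)
        for k in range(policy.multiplier(record.label) - 1):
            clone = perturb_record(record, policy, rng, rules)
            clone.patient_id = f"{record.patient_id}-aug{k + 1}"
            out.append(clone)
    return out
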