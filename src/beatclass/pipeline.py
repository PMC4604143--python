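"""End-to-end two-stage classification of a record and its evaluation.

A preprocessed record is streamed beat by beat: during the 10 s learning
period the reference template is accumulated and no template matching is
possible, so every learning-period beat carries feature defaults and a
Stage-2 decision.  Afterwards each beat is correlated against the template
bank — a reference match is an immediate SVB decision (provenance
"stage1"); all other beats get the 20-feature description (the decision is
delayed until the next beat's Stage-1 outcome is known), the 210-element
expansion and a Stage-2 decision.  The adaptive correlation threshold is
refreshed from each closed 10 s segment's optimal threshold.

Scoring follows the binary SVB (N+S, negative) vs VB (V+F, positive)
accounting; Q-annotated beats run through both stages but are excluded
from every count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from beatclass.signal_io import EcgRecord, composite_leads
from beatclass.stage1 import (
    LEARNING_PERIOD_S,
    MatchOutcome,
    SEGMENT_S,
    TemplateBank,
    extract_beat_contexts,
    find_oct,
    learn_reference,
    match_and_update,
    update_act,
)
from beatclass.features import assemble_basic, expand


@dataclass(frozen=True)
class ConfusionCounts:
    """TN/FP over the SVB class, TP/FN over the VB class."""

    tn: int = 0
    fp: int = 0
    tp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.tp + self.fn


def metrics(counts: ConfusionCounts) -> tuple[float | None, float | None, float | None]:
    """(Se, Sp, PPV) in percent; a zero-denominator metric is None."""
    se = 100.0 * counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else None
    sp = 100.0 * counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp > 0 else None
    ppv = 100.0 * counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp > 0 else None
    return se, sp, ppv


@dataclass
class BeatDecision:
    """Final per-beat result with provenance."""

    index: int
    fiducial: int
    aami: str
    binary: str            # annotated class: SVB / VB / EXCLUDED
    outcome: MatchOutcome
    decision: str          # decided class: SVB / VB
    provenance: str        # "stage1" | "stage2"


@dataclass
class EvalReport:
    stage1: ConfusionCounts
    combined: ConfusionCounts
    v_only: ConfusionCounts
    stage1_metrics: tuple = ()
    combined_metrics: tuple = ()
    v_only_metrics: tuple = ()
    per_record: dict = field(default_factory=dict)


def _snapshot_reference(bank: TemplateBank) -> TemplateBank:
    """Frozen copy of the reference template for feature measurement."""
    import copy

    ref = bank.reference
    snap = TemplateBank(act=bank.act)
    snap.templates.append(copy.deepcopy(ref))
    return snap


def run_two_stage(
    record: EcgRecord,
    stage2_model,
    learning_s: float = LEARNING_PERIOD_S,
    segment_s: float = SEGMENT_S,
) -> tuple[list[BeatDecision], TemplateBank]:
    """Run Stage 1 + Stage 2 over a preprocessed 250 Hz record.

    ``stage2_model`` is any fitted classifier taking the 210-element
    expanded vector (optionally restricted via its ``feature_idx_``
    attribute, as set by the stepwise trainer). Returns the per-beat
    decisions and the final template bank.
    """
    if len(record) < learning_s * record.fs:
        raise ValueError("record shorter than the learning period")
    leads = composite_leads(record)
    contexts = extract_beat_contexts(record, leads)
    anns = [a for a in record.annotations]
    # contexts align with the subset of annotations that had margin; rebuild map
    ctx_by_fid = {c.fiducial: c for c in contexts}
    scored = [(i, a, ctx_by_fid[a.fiducial]) for i, a in enumerate(anns)
              if a.fiducial in ctx_by_fid]

    learn_limit = learning_s * record.fs
    learning = [c for _, _, c in scored if c.fiducial < learn_limit]
    bank = learn_reference(learning) if learning else None

    # Stage-1 pass: outcome per beat, streaming ACT updates per 10 s segment.
    # The reference is snapshotted at each beat's arrival so that F6-F8 and
    # the reference-template features reflect the template state the beat saw.
    outcomes: list[MatchOutcome] = []
    ref_snapshots: list[TemplateBank | None] = []
    seg_len = segment_s * record.fs
    seg_windows: list[np.ndarray] = []
    current_seg = 1  # segment 0 is the learning period, already consumed
    for _, _, ctx in scored:
        if ctx.fiducial < learn_limit or bank is None:
            outcomes.append(MatchOutcome.NONE)
            ref_snapshots.append(None)
            continue
        seg = int(ctx.fiducial // seg_len)
        if seg > current_seg:
            # close the previous segment: OCT -> ACT
            prev = bank.oct_history[-1] if bank.oct_history else None
            oct_val = find_oct(seg_windows, prev_oct=prev)
            bank.oct_history.append(oct_val)
            bank.act = update_act(bank.act, oct_val)
            bank.segment_index = seg
            seg_windows = []
            current_seg = seg
        seg_windows.append(ctx.vel_window)
        ref_snapshots.append(_snapshot_reference(bank))
        outcomes.append(match_and_update(ctx, bank, beat_index=len(outcomes)))

    # Stage-2 pass with delayed decisions (next beat's outcome is known here)
    feature_idx = getattr(stage2_model, "feature_idx_", None)
    decisions: list[BeatDecision] = []
    rr_all = [c.rr_cur for _, _, c in scored]
    fids = [c.fiducial for _, _, c in scored]
    need_stage2 = [k for k in range(len(scored))
                   if outcomes[k] is not MatchOutcome.MATCHED_REFERENCE]
    stage2_X = []
    for k in need_stage2:
        _, _, ctx = scored[k]
        prev_ctx = scored[k - 1][2] if k > 0 else None
        next_ctx = scored[k + 1][2] if k + 1 < len(scored) else None
        in_learning = ctx.fiducial < learn_limit
        rr_last4 = [r for r in rr_all[max(k - 4, 0):k] if np.isfinite(r)]
        t0 = ctx.fiducial - 10.0 * record.fs
        rr_10s = [rr_all[j] for j in range(len(scored))
                  if t0 <= fids[j] <= ctx.fiducial and np.isfinite(rr_all[j])]
        basic = assemble_basic(
            ctx, prev_ctx, next_ctx,
            None if in_learning else ref_snapshots[k],
            outcome=outcomes[k],
            prev_outcome=outcomes[k - 1] if k > 0 else None,
            next_outcome=outcomes[k + 1] if k + 1 < len(scored) else None,
            rr_last4=rr_last4, rr_10s=rr_10s,
        )
        stage2_X.append(expand(basic))
    if stage2_X:
        X = np.stack(stage2_X)
        if feature_idx is not None:
            X = X[:, feature_idx]
        stage2_pred = stage2_model.predict(X)
    else:
        stage2_pred = np.array([])

    pred_iter = iter(stage2_pred)
    for k, (i, ann, ctx) in enumerate(scored):
        if outcomes[k] is MatchOutcome.MATCHED_REFERENCE:
            decision, provenance = "SVB", "stage1"
        else:
            decision, provenance = str(next(pred_iter)), "stage2"
        decisions.append(BeatDecision(
            index=i, fiducial=ctx.fiducial, aami=ann.aami, binary=ann.binary,
            outcome=outcomes[k], decision=decision, provenance=provenance,
        ))
    return decisions, bank


def score_stage1(decisions: list[BeatDecision]) -> ConfusionCounts:
    """Stage-1 accounting: matched-to-reference vs not, Q beats excluded.

    TN = SVB beats matched to the predominant template; FP = SVB beats not
    matched (this includes matches to a secondary template); TP = VB beats
    not matched; FN = VB beats matched.
    """
    tn = fp = tp = fn = 0
    for d in decisions:
        if d.binary == "EXCLUDED":
            continue
        matched = d.outcome is MatchOutcome.MATCHED_REFERENCE
        if d.binary == "SVB":
            tn, fp = tn + matched, fp + (not matched)
        else:
            fn, tp = fn + matched, tp + (not matched)
    return ConfusionCounts(tn=tn, fp=fp, tp=tp, fn=fn)


def score_combined(decisions: list[BeatDecision]) -> EvalReport:
    """Combined (Stage 1 + Stage 2) accounting plus V-only sensitivity.

    TN = SVB beats finally decided SVB (either stage); FP = SVB decided VB;
    TP = VB beats decided VB; FN = VB decided SVB. The V-only figures
    restrict the positive class to V-annotated beats (F beats dropped from
    the positive counts), as commonly reported.
    """
    tn = fp = tp = fn = 0
    tp_v = fn_v = 0
    for d in decisions:
        if d.binary == "EXCLUDED":
            continue
        decided_vb = d.decision == "VB"
        if d.binary == "SVB":
            fp, tn = fp + decided_vb, tn + (not decided_vb)
        else:
            tp, fn = tp + decided_vb, fn + (not decided_vb)
            if d.aami == "V":
                tp_v, fn_v = tp_v + decided_vb, fn_v + (not decided_vb)
    combined = ConfusionCounts(tn=tn, fp=fp, tp=tp, fn=fn)
    v_only = ConfusionCounts(tn=tn, fp=fp, tp=tp_v, fn=fn_v)
    stage1 = score_stage1(decisions)
    return EvalReport(
        stage1=stage1, combined=combined, v_only=v_only,
        stage1_metrics=metrics(stage1),
        combined_metrics=metrics(combined),
        v_only_metrics=metrics(v_only),
    )
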