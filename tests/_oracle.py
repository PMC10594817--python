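"""Independent straight-line re-implementations used as test oracles.

These deliberately avoid the package's internals: the adjudicator below
re-derives every quantity longhand from the raw course so it can serve
as a brute-force cross-check for ``assess_patient``.
"""

from __future__ import annotations

import math


def oracle_assess(course, config):
    """Longhand adjudication of one patient course.

    Returns a dict with baseline_sld, per-scan (sld, category) pairs,
    progression_day, bor (category, day), delta_sld, pfs_day and
    pfs_event — or None when no baseline lesion is measurable.
    Categories are plain strings.
    """
    base = course.scans[0]
    eligible = []
    for m in base.measurements:
        if config.eligibility_dimension == "smallest":
            dim = m.smallest_diameter
        else:
            dim = m.longest_diameter
        if dim is not None and dim >= config.measurable_cutoff:
            eligible.append(m)
    eligible.sort(key=lambda m: (-m.longest_diameter, m.lesion_id))
    targets = {m.lesion_id for m in eligible[: config.max_targets]}
    if not targets:
        return None

    base_ids = {m.lesion_id for m in base.measurements}
    baseline_sld = sum(
        m.longest_diameter for m in base.measurements if m.lesion_id in targets
    )

    # raw walk under the base rules
    slds, nadirs, cats, flags, days = [], [], [], [], []
    seen_new: set[str] = set()
    nadir = baseline_sld
    for scan in course.scans[1:]:
        seen_new |= {m.lesion_id for m in scan.measurements} - base_ids
        s = sum(m.longest_diameter for m in scan.measurements if m.lesion_id in targets)
        if config.new_lesion_policy == "add_to_sld":
            s += sum(
                m.longest_diameter for m in scan.measurements if m.lesion_id in seen_new
            )
        nadir = min(nadir, s)
        pd_call = False
        if config.new_lesion_policy == "immediate_pd" and seen_new:
            pd_call = True
        if scan.non_target_pd:
            pd_call = True
        if s >= nadir * (1 + config.pd_threshold) and s - nadir >= config.pd_absolute:
            pd_call = True
        if pd_call:
            cat = "PD"
        elif s == 0 and not seen_new:
            cat = "CR"
        elif baseline_sld > 0 and s <= baseline_sld * (1 - config.pr_threshold):
            cat = "PR"
        else:
            cat = "SD"
        slds.append(s)
        nadirs.append(nadir)
        cats.append(cat)
        flags.append(scan.non_target_pd)
        days.append(scan.scan_day)

    def size_only_cat(s):
        if s == 0 and not seen_new:
            return "CR"
        if baseline_sld > 0 and s <= baseline_sld * (1 - config.pr_threshold):
            return "PR"
        return "SD"

    progression_day = None
    if config.confirmation is None:
        for d, c in zip(days, cats):
            if c == "PD":
                progression_day = d
                break
        final = cats
    else:
        window = config.confirmation.window_days
        confirm = config.confirmation.confirm_days
        final = list(cats)
        i = 0
        while i < len(final):
            if final[i] != "PD":
                i += 1
                continue
            if days[i] > window:
                progression_day = days[i]
                break
            final[i] = "preliminary_PD"
            qual = None
            for j in range(i + 1, len(final)):
                if days[j] - days[i] >= confirm:
                    qual = j
                    break
            if qual is None:
                break  # unconfirmed, censored
            meets = (
                slds[qual] >= nadirs[i] * (1 + config.pd_threshold)
                and slds[qual] - nadirs[i] >= config.pd_absolute
            ) or (cats[qual] == "PD" and flags[qual])
            if meets:
                progression_day = days[i]
                break
            for j in range(i, qual):
                if final[j] in ("PD", "preliminary_PD"):
                    final[j] = size_only_cat(slds[j])
            i = qual

    # best overall response before progression
    rank = {"CR": 0, "PR": 1, "SD": 2, "preliminary_PD": 2}
    best = None
    for d, c, s in zip(days, final, slds):
        if progression_day is not None and d >= progression_day:
            break
        if c in rank:
            if best is None or rank[c] < rank[best[0]]:
                best = (c if c != "preliminary_PD" else "SD", d, s)
    if best is None:
        bor = ("PD", days[0], slds[0])
    else:
        bor = best

    if progression_day is not None:
        pfs_day = progression_day
        if course.os_event:
            pfs_day = min(pfs_day, course.os_day)
        pfs_event = True
    elif course.os_event:
        pfs_day, pfs_event = course.os_day, True
    else:
        pfs_day, pfs_event = course.last_imaging_day, False

    return {
        "baseline_sld": baseline_sld,
        "slds": slds,
        "categories": final,
        "progression_day": progression_day,
        "bor_category": bor[0],
        "bor_day": bor[1],
        "delta_sld": bor[2] - baseline_sld,
        "pfs_day": pfs_day,
        "pfs_event": pfs_event,
    }


def oracle_weighted_kappa(a, b, order):
    """Cell-by-cell quadratic weighted kappa (plain loops)."""
    k = len(order)
    idx = {c: i for i, c in enumerate(order)}
    n = len(a)
    obs_num = 0.0
    for x, y in zip(a, b):
        obs_num += (idx[x] - idx[y]) ** 2 / (k - 1) ** 2
    row = [0] * k
    col = [0] * k
    for x in a:
        row[idx[x]] += 1
    for y in b:
        col[idx[y]] += 1
    exp_num = 0.0
    for i in range(k):
        for j in range(k):
            exp_num += (i - j) ** 2 / (k - 1) ** 2 * row[i] * col[j] / n
    if exp_num == 0:
        return 1.0
    return 1.0 - obs_num / exp_num


def oracle_mcnemar(b, c):
    """Exact two-sided McNemar p from binomial enumeration."""
    n = b + c
    if n == 0:
        return 1.0
    m = min(b, c)
    tail = sum(math.comb(n, i) for i in range(m + 1)) / 2**n
    return min(1.0, 2 * tail)
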