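"""Independent brute-force oracles: plain loops, no shared code with the
package implementation.  Used by the metric and acceptance suites."""


def oracle_confusion(preds, masks, thr):
    tp = fp = fn = tn = 0
    for p, m in zip(preds, masks):
        for i in range(p.shape[0]):
            for j in range(p.shape[1]):
                hard = p[i, j] >= thr
                truth = m[i, j] > 0
                tp += hard and truth
                fp += hard and not truth
                fn += (not hard) and truth
                tn += (not hard) and not truth
    return tp, fp, fn, tn


def oracle_aupr(scores, labels):
    """Average precision by explicit descending-threshold sweep."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    total_pos = sum(labels)
    tp = fp = 0
    area = 0.0
    i = 0
    prev_recall = 0.0
    while i < len(order):
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            tp += labels[order[j]] == 1
            fp += labels[order[j]] == 0
            j += 1
        recall = tp / total_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


def oracle_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


def oracle_ece(probs, labels, n_bins):
    total = 0.0
    for b in range(n_bins):
        lo, hi = b / n_bins, (b + 1) / n_bins
        sel = [i for i, p in enumerate(probs)
               if (lo <= p < hi) or (b == n_bins - 1 and p == 1.0)]
        if not sel:
            continue
        conf = sum(probs[i] for i in sel) / len(sel)
        acc = sum(labels[i] for i in sel) / len(sel)
        total += len(sel) / len(probs) * abs(acc - conf)
    return total


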