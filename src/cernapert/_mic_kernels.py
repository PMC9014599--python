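"""Numba kernels for the ApproxMaxMI estimator of the maximal information
coefficient.

The characteristic-matrix search follows the published MINE procedure: for
each admissible row count the row axis is equipartitioned (respecting ties),
the column axis is pre-segmented into clumps (maximal runs of points sharing
a row, tied column values never split), clumps are coarsened to at most
``c * max_cols`` superclumps, and dynamic programming over clump boundaries
maximizes mutual information for every admissible column count.  Both axis
orientations are searched and the best normalized score kept.

Everything operates on ranks/orders only, so MIC is exactly invariant under
strictly increasing transforms of either variable.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LN2 = 0.6931471805599453


@njit(cache=True)
def _equipartition(sorted_vals, n_rows, assign):
    """Assign ~n/n_rows points per row over values sorted ascending.

    Tied values are never split across rows.  Returns the number of rows
    actually used (may be < n_rows under heavy ties).
    """
    n = sorted_vals.shape[0]
    i = 0
    row = 0
    count = 0
    assigned = 0
    desired = n / n_rows
    while i < n:
        j = i + 1
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        m = j - i
        if count != 0 and row < n_rows - 1 and \
                abs(count + m - desired) >= abs(count - desired):
            row += 1
            count = 0
            desired = (n - assigned) / (n_rows - row)
        for t in range(i, j):
            assign[t] = row
        count += m
        assigned += m
        i = j
    return row + 1


@njit(cache=True)
def _clump_sizes(col_sorted_vals, rows_in_col_order, sizes):
    """Segment points (in column order) into clumps.

    A clump is a maximal run of consecutive points in the same row; a group
    of tied column values spanning several rows forms its own unsplittable
    clump.  Returns the number of clumps; ``sizes[k]`` is the point count of
    clump k.
    """
    n = col_sorted_vals.shape[0]
    k = 0
    i = 0
    cur_label = -2  # -2: nothing open; -1: mixed-tie clump label (never merges)
    cur_size = 0
    while i < n:
        j = i + 1
        while j < n and col_sorted_vals[j] == col_sorted_vals[i]:
            j += 1
        # does the tied group sit in a single row?
        single = True
        r0 = rows_in_col_order[i]
        for t in range(i + 1, j):
            if rows_in_col_order[t] != r0:
                single = False
                break
        if single and r0 == cur_label:
            cur_size += j - i
        else:
            if cur_size > 0:
                sizes[k] = cur_size
                k += 1
            cur_size = j - i
            cur_label = r0 if single else -1
            if not single:
                # close immediately so the next group starts a fresh clump
                sizes[k] = cur_size
                k += 1
                cur_size = 0
                cur_label = -2
        i = j
    if cur_size > 0:
        sizes[k] = cur_size
        k += 1
    return k


@njit(cache=True)
def _superclump_sizes(sizes, k, k_hat, out):
    """Coarsen k clumps to at most k_hat superclumps by point-count equipartition."""
    total = 0
    for i in range(k):
        total += sizes[i]
    m = 0
    count = 0
    assigned = 0
    groups = 0
    desired = total / k_hat
    for i in range(k):
        s = sizes[i]
        if count != 0 and groups < k_hat - 1 and \
                abs(count + s - desired) >= abs(count - desired):
            out[m] = count
            m += 1
            groups += 1
            count = 0
            desired = (total - assigned) / (k_hat - groups)
        count += s
        assigned += s
    if count > 0:
        out[m] = count
        m += 1
    return m


@njit(cache=True)
def _best_mi_by_cols(cumhist, cumcnt, k, n_rows, max_cols, xlogx, n, g, dp, out):
    """DP over clump boundaries: out[l] = max Σ_cols m_q ln m_q - m ln m
    over partitions of all points into at most l columns, l = 2..max_cols."""
    # g[s, t] for 0 <= s < t <= k : contribution of a column spanning clumps s+1..t
    for s in range(k):
        for t in range(s + 1, k + 1):
            m = cumcnt[t] - cumcnt[s]
            acc = -xlogx[m]
            for q in range(n_rows):
                acc += xlogx[cumhist[t, q] - cumhist[s, q]]
            g[s, t] = acc
    for t in range(1, k + 1):
        dp[t, 1] = g[0, t]
    for l in range(2, max_cols + 1):
        for t in range(1, k + 1):
            best = dp[t, l - 1]  # fewer columns always allowed
            lo = l - 1 if l - 1 < t else t - 1
            for s in range(1, t):
                v = dp[s, l - 1] + g[s, t]
                if v > best:
                    best = v
            dp[t, l] = best
        out[l] = dp[k, l]


@njit(cache=True)
def _mic_kernel(xv, yv, xorder, yorder, limit, c):
    """MIC score: max over grid shapes with rows*cols <= limit (rows,cols >= 2)
    of I(grid)/log2(min(rows, cols)), grids optimized by ApproxMaxMI."""
    n = xv.shape[0]
    xlogx = np.zeros(n + 1)
    for i in range(2, n + 1):
        xlogx[i] = i * np.log(i)
    max_rows = limit // 2
    best = 0.0
    assign = np.empty(n, dtype=np.int64)
    rows_in_col_order = np.empty(n, dtype=np.int64)
    sizes = np.empty(n + 1, dtype=np.int64)
    sizes2 = np.empty(n + 1, dtype=np.int64)
    for orient in range(2):
        if orient == 0:
            rv, ro = yv, yorder  # rows from y
            cv, co = xv, xorder  # cols from x
        else:
            rv, ro = xv, xorder
            cv, co = yv, yorder
        r_sorted = rv[ro]
        row_of = np.empty(n, dtype=np.int64)
        for n_rows in range(2, max_rows + 1):
            max_cols = limit // n_rows
            if max_cols < 2:
                break
            used = _equipartition(r_sorted, n_rows, assign)
            if used < 2:
                continue
            for i in range(n):
                row_of[ro[i]] = assign[i]
            # row entropy term (nats, scaled by n): Σ n_q ln n_q
            rowcnt = np.zeros(used, dtype=np.int64)
            for i in range(n):
                rowcnt[row_of[i]] += 1
            sum_q = 0.0
            for q in range(used):
                sum_q += xlogx[rowcnt[q]]
            h_q = np.log(n) - sum_q / n
            for i in range(n):
                rows_in_col_order[i] = row_of[co[i]]
            k = _clump_sizes(cv[co], rows_in_col_order, sizes)
            k_hat = c * max_cols
            if k_hat < 1:
                k_hat = 1
            if k > k_hat:
                k = _superclump_sizes(sizes, k, k_hat, sizes2)
                use_sizes = sizes2
            else:
                use_sizes = sizes
            if k < 2:
                continue
            cumcnt = np.zeros(k + 1, dtype=np.int64)
            cumhist = np.zeros((k + 1, used), dtype=np.int64)
            pos = 0
            for t in range(1, k + 1):
                cumcnt[t] = cumcnt[t - 1] + use_sizes[t - 1]
                for q in range(used):
                    cumhist[t, q] = cumhist[t - 1, q]
                for _ in range(use_sizes[t - 1]):
                    cumhist[t, rows_in_col_order[pos]] += 1
                    pos += 1
            g = np.zeros((k, k + 1))
            dp = np.full((k + 1, max_cols + 1), -1e300)
            out = np.zeros(max_cols + 1)
            _best_mi_by_cols(cumhist, cumcnt, k, used, max_cols, xlogx, n, g, dp, out)
            for l in range(2, max_cols + 1):
                if l * n_rows > limit:
                    break
                i_nats = h_q + out[l] / n
                if i_nats < 0.0:
                    i_nats = 0.0
                denom = n_rows if n_rows < l else l
                score = (i_nats / _LN2) / np.log2(denom)
                if score > best:
                    best = score
    if best > 1.0:
        best = 1.0
    return best
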