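"""The proportional reporting ratio on a small worked example.

With m = 10 anosmia reports among n = 100 index-vaccine reports, and
M = 20 anosmia reports among N = 300 reports database-wide, the background
proportion is (M-m)/(N-n) = 10/200, so PRR = (10/100)/(10/200) = 2.
"""
from otosignal import prr, prr_ci, prr_result

m, n, M, N = 10, 100, 20, 300
print(f"PRR  = {prr(m, n, M, N):.3f}")
low, high = prr_ci(m, n, M, N)
print(f"95% CI = ({low:.3f}, {high:.3f})")

result = prr_result("Anosmia", m, n, M, N)
print(f"signal at threshold 2: {result.signal}")

# The interval is the log-normal (delta-method) one:
# exp(ln PRR +/- 1.96 * sqrt(1/m - 1/n + 1/(M-m) - 1/(N-n))).
# Here it spans ~0.86-4.65: the point estimate sits at the signal
# threshold, but m = 10 is far too few reports to pin the ratio down.
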