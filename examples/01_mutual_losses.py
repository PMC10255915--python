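"""Mutual-learning loss arithmetic on two toy students.

Two students predict distributions over six behavior classes for the
same clip.  Each student's loss is its cross-entropy against the label
plus the KL divergence from its peer's posterior toward its own; the
stream loss mixes the two with weight alpha.
"""

import numpy as np

from tsml import mutual_stream_loss, softmax_probs

# raw classifier scores over [drinking, eating, fighting, investigating,
# lying, walking]; the true class is index 5 (walking)
logits1 = np.array([0.1, 0.4, -0.3, 0.2, -0.8, 1.5])
logits2 = np.array([-0.2, 0.1, 0.3, 0.6, -0.5, 1.1])
y = 5

p1, p2 = softmax_probs(logits1), softmax_probs(logits2)
print("student 1 posterior:", np.round(p1, 3))
print("student 2 posterior:", np.round(p2, 3))

breakdown = mutual_stream_loss(p1, p2, y, alpha=0.5)
print(f"student 1: ce={breakdown.student1.ce:.4f} nats, "
      f"kl={breakdown.student1.kl:.4f} nats, total={breakdown.student1.total:.4f}")
print(f"student 2: ce={breakdown.student2.ce:.4f} nats, "
      f"kl={breakdown.student2.kl:.4f} nats, total={breakdown.student2.total:.4f}")
print(f"stream loss (alpha=0.5): {breakdown.stream:.4f} nats")
print()
print("The ce terms measure each student's own fit to the label; the kl")
print("terms pull the two posteriors together. Agreeing students would have")
print("kl = 0 and the stream loss would reduce to the mean cross-entropy.")
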