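"""Encode a handful of medical tokens into model input vectors.

Shows the three encoding pieces: one-hot concepts for boolean tokens, the
"1-value" encoding (one-hot scaled by the measurement) for value tokens, and
the sinusoidal time embedding of the timestamp in hours.
"""

import numpy as np

from kuq.synthetic_ehr import MedicalToken, PatientEpisode, default_vocabulary
from kuq.token_encoding import embed_episode, encode_value_token, time_embedding

vocab = default_vocabulary()
print(f"vocabulary: {vocab.size} concepts "
      f"({len(vocab.value_concepts())} value, "
      f"{vocab.size - len(vocab.value_concepts())} boolean)")

vec = encode_value_token("heart_rate", 88.0, vocab)
print(f"\n'heart rate = 88 bpm' -> nonzero entry {vec.max():.0f} at index "
      f"{int(np.argmax(vec))} (the heart-rate slot); all other entries are 0")

emb = time_embedding(12.0, width=8)
print(f"time embedding of t=12 h (width 8): {np.round(emb, 3)}")
print("each (sin, cos) pair lies on the unit circle; pairs rotate at "
      "geometrically spaced frequencies, so nearby times get nearby codes")

episode = PatientEpisode(
    tokens=[MedicalToken(0.0, "heart_rate", 88.0),
            MedicalToken(1.0, "gcs_verbal_confused"),
            MedicalToken(2.0, "sbp", 125.0)],
    label=0, episode_id="demo")
mat = embed_episode(episode, vocab, time_width=8)
print(f"\nembedded episode: {mat.shape[0]} tokens x {mat.shape[1]} dims "
      f"({vocab.size} concept dims + 8 time dims per row)")
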