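"""A scripted interview with a child avatar, then automated feedback.

Runs a short mixed-quality interview against a 4-year-old abused avatar,
prints each coded turn with the avatar's answer, the five outcome
measures (question and detail counts), and the feedback report with the
case outcome plus comments on two recommended and two not-recommended
questions sampled from the transcript.
"""

import numpy as np

from interviewsim import (
    AvatarProfile,
    BoosterConfig,
    SessionConfig,
    balanced_spec,
    build_scenario_pack,
    default_rule_config,
    generate_corpus,
    generate_feedback,
    run_interview,
    summarize,
    tune_and_train,
)

df = generate_corpus(balanced_spec(per_class=30, seed=11))
model = tune_and_train(
    df["text"].tolist(), df["label"].tolist(),
    booster_cfg=BoosterConfig(n_estimators=60, min_child_weight=2, learning_rate=0.3),
    seed=5, cv=False, rebalance=False,
)
rules = default_rule_config()
pack = build_scenario_pack(AvatarProfile("demo", age=4, gender="girl", abused=True), seed=2)

script = [
    "Hello",
    "Tell me everything that happened from the beginning to the end",
    "Tell me about your dad",
    "Go ahead",
    "Did your dad hurt you?",
    "Did your dad hurt you?",
    "Was it the park or the garden?",
    "Tell me more about that day",
]
t = run_interview(script, pack, model, rules, SessionConfig(max_turns=20, seed=4))

for turn in t.turns:
    label = getattr(turn.classified.qtype, "value", turn.classified.qtype)
    print(f"[{label:<22}] {turn.question_text}")
    print(f"{'':24} child: {turn.response.text}  ({turn.response.detail_kind})")

s = summarize(t)
print("\noutcome measures:", s.as_dict())
print("(recommended questions earn relevant details; suggestive and")
print(" repeated questions risk creating incorrect ones)")

print("\n" + generate_feedback(t, pack, np.random.default_rng(6)).to_markdown())
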