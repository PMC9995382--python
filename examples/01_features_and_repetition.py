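"""N-gram featurization and Jaccard repetition detection.

Builds word-bigram and character N-gram features for a few interviewer
questions and shows how the Jaccard coefficient of consecutive feature
sets flags a re-asked question.
"""

from interviewsim import FeaturizerConfig, extract_ngrams, jaccard

bigrams = FeaturizerConfig(unit="word", n_min=2, n_max=2)
print("word bigrams of 'Tell me what happened':")
print(" ", extract_ngrams("Tell me what happened", bigrams))

chars = FeaturizerConfig()  # character units, N = 1..5 (the default)
q1 = "Did you go to the park?"
q2 = "Did you go to the park?"
q3 = "Tell me about your family"
f1, f2, f3 = (extract_ngrams(q, chars) for q in (q1, q2, q3))

print(f"\njaccard(identical re-ask)  = {jaccard(f1, f2):.3f}")
print(f"jaccard(different question) = {jaccard(f1, f3):.3f}")
print(
    "\nWith the default threshold 0.5, the first pair is coded as a"
    "\nrepetition (similarity 1.0) and the second is not."
)
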