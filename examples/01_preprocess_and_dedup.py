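"""Clean raw short texts and drop near-duplicates.

Builds a handful of tweet-like posts, normalises them (URL/emoji removal,
sigil stripping, stopword filtering, plural normalisation) and removes
near-duplicates by hash + embedding cosine similarity.
"""

from shorttopic import (
    DedupConfig,
    EmbedderSpec,
    RawDocument,
    clean_corpus,
    deduplicate,
    embed_documents,
)

posts = [
    RawDocument("t1", "@Aaron_GDAC Excited for you! I'll be working on more "
                      "portraits and training as a child &amp; adolescent "
                      "mental health coach!"),
    RawDocument("t2", "Teens are losing sleep over social media \U0001F634 "
                      "https://example.org/study"),
    RawDocument("t3", "Teens are losing sleep over social media "
                      "https://example.org/other-link"),
    RawDocument("t4", "School counselors talk anxiety, stress and coping."),
]

clean = clean_corpus(posts)
for doc in clean:
    print(f"{doc.id}: {doc.text_norm}")

vectors = embed_documents(clean, EmbedderSpec(dim=64, seed=0))
kept, report = deduplicate(clean, vectors, DedupConfig(epsilon=0.95))
print(f"\nkept {len(kept)} of {len(clean)} documents")
for dropped, kept_id, sim in report:
    print(f"dropped {dropped} (similarity {sim:.3f} to {kept_id})")

# t2 and t3 normalise to the same token sequence once their URLs are
# stripped, so the later one is removed as an exact duplicate.
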