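"""Packaged English stop-word list.

A fixed, versioned list so that tokenization — and therefore every TF-IDF
value — is reproducible across installations. Roughly the classic SMART/
Glasgow core function words; deliberately frozen rather than delegated to an
external resource whose contents can drift between releases.
"""

ENGLISH_STOPWORDS = frozenset("""
a about above after again against all am an and any are as at
be because been before being below between both but by
can cannot could
did do does doing down during
each
few for from further
had has have having he her here hers herself him himself his how
i if in into is it its itself
just
me more most my myself
no nor not now
of off on once only or other our ours ourselves out over own
same she should so some such
than that the their theirs them themselves then there these they this those
through to too
under until up
very
was we were what when where which while who whom why will with would
you your yours yourself yourselves
""".split())
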