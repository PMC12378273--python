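# Adolescent-health domain vocabulary used by the popularity-deviation
# regularizer to boost domain-specific terms. One entry per line; multiword
# entries are matched through their component tokens (or as bigrams when a
# bigram vocabulary is enabled).
sleep
stress
depression
anxiety
nutrition
bullying
self-harm
substance
screen
cyber
mental health
wellbeing
addiction
mindfulness
exercise
suicide
therapy
meditation
resilience
counseling
psychology
social media
selfcare
trauma
emotion
diagnosis
insomnia
disorder
coping
psychotherapy
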