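# Default MedDRA preferred-term -> adverse-event-group mapping.
#
# The 19 group names are the canonical otolaryngologic AEFI group labels;
# each group is seeded with the preferred terms literally named in its
# label plus immediate MedDRA spelling variants. A production analysis
# should replace these seed lists with the full curated PT list (the
# published grouping covers 153 PTs); the group names must be kept as-is.
unmapped_policy: DROP
groups:
  Hearing loss:
    - Hearing loss
    - Deafness
    - Hypoacusis
    - Sudden hearing loss
  Tinnitus (Ringing in the ears):
    - Tinnitus
    - Tinnitus aggravated
    - Ringing in the ears
  Ear infections (Otitis Media):
    - Ear infection
    - Otitis media
    - Otitis media acute
  Meniere’s disease:
    - Meniere's disease
    - Meniere’s disease
  Vestibular neuronitis:
    - Vestibular neuronitis
    - Neuronitis vestibular
  Dizziness or vertigo:
    - Dizziness
    - Vertigo
    - Vertigo positional
  Sinusitis:
    - Sinusitis
    - Sinusitis acute
    - Sinusitis chronic
  Rhinitis (Allergic and Non-allergic):
    - Rhinitis
    - Rhinitis allergic
  Epistaxis:
    - Epistaxis
  Anosmia:
    - Anosmia
    - Hyposmia
  Nasal polyps:
    - Nasal polyps
  Snoring or difficulty breathing through the nose and sleep apnea:
    - Snoring
    - Nasal obstruction
    - Sleep apnoea syndrome
  Allergies:
    - Allergy
    - Hypersensitivity
    - Seasonal allergy
  Tonsillitis:
    - Tonsillitis
  Laryngitis:
    - Laryngitis
  Vocal cord polyps and nodules:
    - Vocal cord polyp
    - Vocal cord nodule
  Laryngopharyngeal reflux (acid reflux):
    - Laryngopharyngeal reflux
    - Acid reflux
  Epiglottitis:
    - Epiglottitis
  Pharyngitis:
    - Pharyngitis
    - Pharyngeal inflammation
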