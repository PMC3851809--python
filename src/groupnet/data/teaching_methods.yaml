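# Menu of teaching methods the interventionist can use when a diagnostic is
# flagged. One numbered list per metric; {placeholders} are filled with the
# display names of the members the finding targets. {group} is the group's
# label. Versioned as data so the wording can evolve without code changes.
isolates:
  - >-
    Pair isolates with highly connected group members in small group
    activities in session: {pairings}.
  - >-
    Call on isolates first to answer questions in session ({isolates}), with
    the goal of not letting them fade into the background; refer back to what
    the isolate said to show their input is valued.
  - >-
    Catch the isolate alone (if possible) and check in with her to let her
    know we care and ask how {group} is going for her, without putting her on
    the spot publicly.
low_degree:
  - >-
    Pair highly connected group members with others in small group activities
    in session: pair {low_degree} with {hubs}.
reciprocity:
  - >-
    Pair non-reciprocated links: if A sends a tie to B, but B does not send a
    tie to A, pair A and B in small group activities in session ({dyads}).
components:
  - >-
    Pair members from different subgroups in small group activities in
    session (create bridges): {bridges}.
  - >-
    Make sure small groups do not split along these lines ({subgroups}); if
    they do, reassign members.
density:
  - >-
    Begin each session with an interactive, personalized, community-building
    ice breaker.
  - >-
    Use a beach ball ("talking stick") to give each participant the
    opportunity to be part of the conversation.
  - >-
    Help the group establish a stronger group identity: at each session
    emphasize (a) the larger {group} family as a support network with a
    shared mission of improving health; (b) that there needs to be balance in
    what people put in and get out of the group, and that the more families
    invest in each other, the more they can get from the group; (c) that all
    parents need and deserve support in the face of our obesogenic
    environment; and (d) that this is the most dedicated group of parents
    committed to the issue of pediatric obesity prevention.
  - >-
    Spend 15 minutes so that each member is offered the opportunity to share
    some relevant aspect of their lives and expectations (personal
    information), using the mutual invitation process to structure such
    sharing.
  - >-
    Facilitate making and meeting a shared common goal.
centralization:
  - >-
    Do not let the central node ({central}) start conversations, be the first
    person to answer a question, lead goal review, or lead group activity; if
    a central person asks to lead a group activity, redirect so that a member
    on the periphery can take on that role.
  - >-
    Avoid pairing central nodes ({central}) with isolates.
transitivity:
  - >-
    Bring triads together in activities in session: if A is friends with B
    and C, connect B and C ({open_triads}).
cohesion:
  - >-
    Challenge the group to make and meet a shared common goal (weekly
    wellness challenge: 15 minutes of walking per day). The group tracks
    their minutes during the week and totals the group's minutes to see
    combined efforts next session; track success each session and increase
    the daily goal in subsequent sessions.
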